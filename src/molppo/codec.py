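"""Robust SELFIES-style molecular string codec.

Molecules are written as sequences of bracketed tokens over a derivation
grammar with the defining property of self-referencing embedded strings:
*every* token sequence over the alphabet decodes to a syntactically valid
molecule.  The decoder enforces valence constraints constructively — a bond
that would exceed an atom's remaining capacity is reduced or dropped, and
derivation stops when the current atom cannot bond further — so generated
strings never need post-hoc validity filtering.

The alphabet covers the neutral organic subset (C, N, O, F, P, S, Cl, Br;
bond orders 1–3; branches; ring closures).  Stereochemistry, formal charges
and isotopes are outside the alphabet: :func:`encode` raises on such input,
:func:`decode` can by construction never produce it.

Branch and ring tokens are followed by one ([Branch1]/[Ring1]) or two
([Branch2]/[Ring2]) index tokens; each alphabet token doubles as an index
digit equal to its alphabet position, so a branch length or ring distance is
read base-``len(alphabet)``.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: maximum bonding capacity per supported element; P is capped at 3 so the
#: decoder can never build hypervalent P that RDKit would charge-separate
VALENCES = {"C": 4, "N": 3, "O": 2, "F": 1, "P": 3, "S": 6, "Cl": 1, "Br": 1}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}

def _atom_tokens() -> list[str]:
    toks = []
    for elem in ["C", "N", "O", "F", "P", "S", "Cl", "Br"]:
        for order in (1, 2, 3):
            if order <= min(VALENCES[elem], 3):
                toks.append(f"[{_BOND_PREFIX[order]}{elem}]")
    return toks


#: full token alphabet; list position doubles as the index-digit value
ALPHABET: list[str] = _atom_tokens() + [
    "[Branch1]", "[Branch2]", "[Ring1]", "[Ring2]", "[=Ring1]", "[=Ring2]",
]
_INDEX = {tok: i for i, tok in enumerate(ALPHABET)}
_BASE = len(ALPHABET)

#: atom tokens parsed once: token -> (bond_order, element)
_ATOMS: dict[str, tuple[int, str]] = {}
for _tok in _atom_tokens():
    _body = _tok[1:-1]
    if _body[0] in "=#":
        _ATOMS[_tok] = (_PREFIX_BOND[_body[0]], _body[1:])
    else:
        _ATOMS[_tok] = (1, _body)


def tokenize(string: str) -> list[str]:
    """Split a bracketed token string like ``[C][=O]`` into tokens."""
    if not string:
        return []
    parts = []
    i = 0
    while i < len(string):
        if string[i] != "[":
            raise ValueError(f"malformed token string at position {i}: {string!r}")
        j = string.index("]", i)
        parts.append(string[i:j + 1])
        i = j + 1
    return parts


def _read_index(tokens: list[str], i: int, n_digits: int) -> int | None:
    """Read an n-digit base-len(alphabet) integer; None if tokens run out."""
    if i + n_digits > len(tokens):
        return None
    value = 0
    for d in range(n_digits):
        tok = tokens[i + d]
        if tok not in _INDEX:
            return None
        value = value * _BASE + _INDEX[tok]
    return value


def _index_tokens(value: int) -> list[str]:
    """Inverse of :func:`_read_index`, choosing the shortest width."""
    if value < _BASE:
        return [ALPHABET[value]]
    if value < _BASE * _BASE:
        return [ALPHABET[value // _BASE], ALPHABET[value % _BASE]]
    raise ValueError(f"index {value} exceeds two-digit capacity")


class _DecodeState:
    __slots__ = ("mol", "caps", "n_atoms")

    def __init__(self):
        self.mol = Chem.RWMol()
        self.caps: list[int] = []
        self.n_atoms = 0

    def add_atom(self, elem: str) -> int:
        atom = Chem.Atom(elem)
        atom.SetNoImplicit(False)
        idx = self.mol.AddAtom(atom)
        self.caps.append(VALENCES[elem])
        self.n_atoms += 1
        return idx

    def add_bond(self, a: int, b: int, order: int) -> None:
        self.mol.AddBond(a, b, Chem.BondType.values[order])
        self.caps[a] -= order
        self.caps[b] -= order


def _derive(tokens: list[str], state: _DecodeState, prev: int | None) -> None:
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in _ATOMS:
            order, elem = _ATOMS[tok]
            if prev is not None and state.caps[prev] <= 0:
                return  # current atom saturated: derivation dead-ends
            idx = state.add_atom(elem)
            if prev is not None:
                bo = min(order, state.caps[prev], state.caps[idx])
                state.add_bond(prev, idx, bo)
            prev = idx
            i += 1
        elif tok in ("[Branch1]", "[Branch2]"):
            n_digits = 1 if tok == "[Branch1]" else 2
            value = _read_index(tokens, i + 1, n_digits)
            if value is None:
                return
            if prev is None or state.caps[prev] < 1:
                # inapplicable branch: drop the symbol and its index digits,
                # the would-be body derives as ordinary tokens
                i += 1 + n_digits
                continue
            length = value + 1
            body = tokens[i + 1 + n_digits: i + 1 + n_digits + length]
            _derive(body, state, prev)
            i += 1 + n_digits + length
        elif tok in ("[Ring1]", "[Ring2]", "[=Ring1]", "[=Ring2]"):
            order = 2 if tok.startswith("[=") else 1
            n_digits = 2 if tok.endswith("2]") else 1
            value = _read_index(tokens, i + 1, n_digits)
            if value is None:
                return
            dist = value + 1
            if prev is not None and dist < state.n_atoms:
                target = state.n_atoms - 1 - dist
                ok = (target != prev
                      and state.mol.GetBondBetweenAtoms(prev, target) is None
                      and state.caps[prev] >= 1 and state.caps[target] >= 1)
                if ok:
                    bo = min(order, state.caps[prev], state.caps[target])
                    state.add_bond(prev, target, bo)
            i += 1 + n_digits
        else:
            raise ValueError(f"unknown token {tok!r}")


def decode(tokens: list[str] | str) -> str:
    """Decode a token sequence to a canonical SMILES string.

    Never raises on any sequence over :data:`ALPHABET`; an empty sequence
    decodes to the empty SMILES.
    """
    if isinstance(tokens, str):
        tokens = tokenize(tokens)
    state = _DecodeState()
    _derive(list(tokens), state, None)
    if state.n_atoms == 0:
        return ""
    mol = state.mol.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def encode(smiles: str) -> list[str]:
    """Encode a SMILES string into a token sequence.

    Raises :class:`ValueError` for unparseable SMILES or molecules outside
    the supported subset (charges, isotopes, radicals, unsupported elements,
    multiple fragments, triple-bond ring closures).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError("multi-fragment molecules are not supported")
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in VALENCES:
            raise ValueError(f"unsupported element {atom.GetSymbol()}")
        if atom.GetFormalCharge() != 0 or atom.GetIsotope() != 0:
            raise ValueError("charges/isotopes are not supported")
        if atom.GetNumRadicalElectrons() != 0:
            raise ValueError("radicals are not supported")

    pos: dict[int, int] = {}
    counter = [0]
    done_bonds: set[int] = set()

    def emit(u: int, parent: int | None, in_order: int) -> list[str]:
        atom = mol.GetAtomWithIdx(u)
        elem = atom.GetSymbol()
        order = min(in_order, 3)
        toks = [f"[{_BOND_PREFIX[order]}{elem}]"]
        pos[u] = counter[0]
        counter[0] += 1
        ring_toks: list[str] = []
        children: list[tuple[int, int]] = []
        for bond in atom.GetBonds():
            v = bond.GetOtherAtomIdx(u)
            bo = int(bond.GetBondTypeAsDouble())
            if v == parent and bond.GetIdx() not in done_bonds:
                done_bonds.add(bond.GetIdx())
                continue
            if bond.GetIdx() in done_bonds:
                continue
            if v in pos:  # back-edge: ring closure
                done_bonds.add(bond.GetIdx())
                dist = pos[u] - pos[v]
                if bo >= 3:
                    raise ValueError("triple-bond ring closures are not supported")
                prefix = "=" if bo == 2 else ""
                digits = _index_tokens(dist - 1)
                ring_toks += [f"[{prefix}Ring{len(digits)}]"] + digits
            else:
                children.append((v, bo))
        toks += ring_toks
        for k, (v, bo) in enumerate(children):
            bond = mol.GetBondBetweenAtoms(u, v)
            if bond.GetIdx() in done_bonds:
                continue
            done_bonds.add(bond.GetIdx())
            if v in pos:
                # became a ring closure while emitting an earlier sibling
                dist_now = counter[0] - 1 - pos[v]
                raise ValueError("unexpected traversal state")  # pragma: no cover
            sub = emit(v, u, bo)
            remaining = [w for w, _ in children[k + 1:] if w not in pos]
            if remaining:
                digits = _index_tokens(len(sub) - 1)
                toks += [f"[Branch{len(digits)}]"] + digits + sub
            else:
                toks += sub
        return toks

    import sys
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        return emit(0, None, 1)
    finally:
        sys.setrecursionlimit(old_limit)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None when unparseable."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)
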