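"""Five-row graph-matrix molecule codec with stepwise valence masking.

A molecule plus a chosen fragment subset is written as an integer matrix
with five rows: atom type, bond type, connected atom index, current atom
index, fragment index.  Columns fall into three sections: the fragment
section (one block per input fragment, fragment index >= 1), the growing
section (new atoms extending the fragments, fragment index 0), and -- after
an end-token column -- the linking section, which joins the grown
components with single bonds.  Molecules are kekulized before encoding so
that per-atom valence sums are well defined; aromaticity is re-perceived by
sanitization on decoding.

During generation the codec's :class:`GraphState` exposes, at every step,
exactly the continuations under which each atom's running bond-order total
stays within its maximum valence -- the mechanism that makes every sampled
matrix decode to a chemically valid molecule.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import MoleculeRecord

logger = logging.getLogger("molgrow")

#: Bond types: index 0 is "no bond" ('*'); 1..3 are single/double/triple.
N_BOND_TYPES = 4
BOND_ORDERS = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}

BLANK_IDX, GO_IDX, END_IDX = 0, 1, 2

_ELEMENTS = ("B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I")


def _default_atom_tokens() -> list[str]:
    tokens = list(_ELEMENTS)
    for sym in _ELEMENTS:
        tokens.append(f"{sym}+1")
        tokens.append(f"{sym}-1")
    return tokens  # 36 atom entries + 3 control tokens


def _parse_atom_token(token: str) -> tuple[str, int]:
    if token.endswith("+1"):
        return token[:-2], 1
    if token.endswith("-1"):
        return token[:-2], -1
    return token, 0


#: Hard caps for halogens: RDKit accepts hypervalent halogens (IF5-like)
#: atom-by-atom, but its sanitization cleanUp pass rewrites halogen-oxide
#: motifs (charge separation), which can invalidate neighbouring atoms.
#: Capping at the organic-chemistry norm keeps the mask sound.
_VALENCE_CAPS = {
    ("F", 0): 1, ("Cl", 0): 1, ("Br", 0): 1, ("I", 0): 1,
    ("F", 1): 0, ("Cl", 1): 2, ("Br", 1): 2, ("I", 1): 2,
    ("F", -1): 0, ("Cl", -1): 0, ("Br", -1): 0, ("I", -1): 0,
}


def _max_valence(symbol: str, charge: int) -> int:
    """Largest explicit bond-order sum RDKit sanitization accepts.

    Determined empirically (atom + k single-bonded carbons) so the valence
    mask agrees exactly with the sanitizer used at decode time; halogens
    are additionally capped at their standard valences.
    """
    cap = _VALENCE_CAPS.get((symbol, charge), 8)
    for k in range(min(cap, 8), -1, -1):
        rw = Chem.RWMol()
        a = Chem.Atom(symbol)
        a.SetFormalCharge(charge)
        rw.AddAtom(a)
        for i in range(k):
            rw.AddAtom(Chem.Atom("C"))
            rw.AddBond(0, i + 1, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(rw.GetMol())
            return k
        except Exception:
            continue
    return 0


def graph_position_index(i_atom: int, i_connected: int, l_max: int) -> int:
    """P = I_atom x L_max + I_connected; injective over index pairs < L_max.

    P feeds the same sinusoidal positional-encoding table as sequence
    positions do in the sequence transformer.
    """
    if not (0 <= i_atom < l_max and 0 <= i_connected < l_max):
        raise ValueError(
            f"atom indices ({i_atom}, {i_connected}) out of range for L_max={l_max}"
        )
    return i_atom * l_max + i_connected


class EncodeError(ValueError):
    pass


class DecodeError(ValueError):
    """Decoding failure; carries the column index of the first inconsistency."""

    def __init__(self, msg: str, column: int | None = None):
        super().__init__(msg if column is None else f"column {column}: {msg}")
        self.column = column


@dataclass
class GraphVocab:
    """Atom-type vocabulary ('*' blank, GO, END, then element tokens).

    The combined word index ``W = T_atom * 4 + T_bond`` is injective over
    (atom, bond) pairs because exactly four bond types exist.
    """

    atom_tokens: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.atom_tokens:
            self.atom_tokens = ["*", "GO", "EOS", *_default_atom_tokens()]
        self.index = {t: i for i, t in enumerate(self.atom_tokens)}
        self.max_valence = np.zeros(len(self.atom_tokens), dtype=np.int64)
        for i, tok in enumerate(self.atom_tokens):
            if i in (BLANK_IDX, GO_IDX, END_IDX):
                continue
            sym, chg = _parse_atom_token(tok)
            self.max_valence[i] = _max_valence(sym, chg)

    def __len__(self):
        return len(self.atom_tokens)

    @property
    def n_words(self) -> int:
        return len(self.atom_tokens) * N_BOND_TYPES

    def word_index(self, t_atom: int, t_bond: int) -> int:
        """W = T_atom x 4 + T_bond (4 = number of bond types); injective."""
        if not 0 <= t_bond < N_BOND_TYPES:
            raise ValueError(f"bond type {t_bond} out of range")
        if not 0 <= t_atom < len(self.atom_tokens):
            raise ValueError(f"atom type {t_atom} out of range")
        return t_atom * N_BOND_TYPES + t_bond

    def atom_index(self, symbol: str, charge: int) -> int:
        token = symbol if charge == 0 else f"{symbol}{'+' if charge > 0 else '-'}{abs(charge)}"
        if token not in self.index:
            raise EncodeError(f"atom token {token!r} not in vocabulary")
        return self.index[token]

    def make_atom(self, t_atom: int) -> Chem.Atom:
        sym, chg = _parse_atom_token(self.atom_tokens[t_atom])
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(chg)
        return atom

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.atom_tokens) + "\n")

    @classmethod
    def load(cls, path) -> "GraphVocab":
        with open(path) as fh:
            return cls([line.rstrip("\n") for line in fh if line.rstrip("\n")])


@dataclass
class GraphMatrix:
    """Columns of the five-row representation (shape 5 x n_columns)."""

    data: np.ndarray  # int64, shape (5, n)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[0] != 5:
            raise ValueError("graph matrix must have five rows")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def split_sections(self) -> tuple[np.ndarray, np.ndarray]:
        """(encoder columns: GO + fragment sections, decoder columns: rest)."""
        frag_row = self.data[4]
        atom_row = self.data[0]
        n_enc = 1
        while n_enc < self.n_columns and frag_row[n_enc] >= 1:
            n_enc += 1
        if atom_row[0] != GO_IDX:
            raise ValueError("matrix must start with the GO column")
        return self.data[:, :n_enc], self.data[:, n_enc:]

    def to_tsv(self, path) -> None:
        np.savetxt(path, self.data, fmt="%d", delimiter="\t")

    @classmethod
    def from_tsv(cls, path) -> "GraphMatrix":
        return cls(np.loadtxt(path, dtype=np.int64, delimiter="\t", ndmin=2))


# ---------------------------------------------------------------------------
# encoding


def _match_fragments(rdmol: Chem.Mol, fragments) -> list[tuple[int, ...]]:
    """Map each fragment SMILES onto disjoint atom sets of the molecule.

    Backtracks over the candidate substructure matches so that a greedy
    early placement cannot block a later fragment.
    """
    candidates = []
    for frag in fragments:
        query = Chem.MolFromSmiles(frag)
        if query is None:
            raise EncodeError(f"unparsable fragment {frag!r}")
        matches = rdmol.GetSubstructMatches(query, uniquify=True, maxMatches=256)
        if not matches:
            raise EncodeError(f"fragment {frag!r} not found in molecule")
        candidates.append(matches)

    # most-constrained fragments (fewest candidate placements) first
    order = sorted(range(len(fragments)), key=lambda i: len(candidates[i]))
    placed: dict[int, tuple[int, ...]] = {}

    def search(pos: int, used: frozenset) -> bool:
        if pos == len(order):
            return True
        i = order[pos]
        for match in candidates[i]:
            if used.isdisjoint(match):
                placed[i] = match
                if search(pos + 1, used | frozenset(match)):
                    return True
        return False

    if not search(0, frozenset()):
        raise EncodeError(
            f"fragments {list(fragments)!r} cannot be placed disjointly in molecule"
        )
    return [placed[i] for i in range(len(fragments))]


def encode_graph(
    mol: MoleculeRecord, fragments, vocab: GraphVocab | None = None
) -> GraphMatrix:
    """Encode a molecule and its fragment subset into the five-row matrix.

    The molecule is kekulized; fragment columns come first (fragment index
    1..n in the last row), then growing columns that extend each fragment's
    atoms, an end-token column, single-bond linking columns, and a final
    end-token column.
    """
    vocab = vocab or GraphVocab()
    if isinstance(fragments, str):
        fragments = fragments.split(".")
    rdmol = mol.mol()
    matches = _match_fragments(rdmol, fragments)

    kek = Chem.Mol(rdmol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - rare
        raise EncodeError(f"cannot kekulize {mol.smiles!r}: {exc}") from exc

    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=True))
    bond_order = {}
    for b in kek.GetBonds():
        o = int(b.GetBondTypeAsDouble())
        if o not in (1, 2, 3):
            raise EncodeError(f"unsupported bond order {o} in {mol.smiles!r}")
        bond_order[frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))] = o

    def neighbors(i):
        return sorted(
            (a.GetIdx() for a in kek.GetAtomWithIdx(i).GetNeighbors()),
            key=lambda j: ranks[j],
        )

    # group assignment: nearest fragment by BFS; record the BFS parent so
    # every growing atom attaches inside its own group
    group = {a: gi + 1 for gi, match in enumerate(matches) for a in match}
    parent: dict[int, int] = {}
    frontier = deque(
        sorted((a for m in matches for a in m), key=lambda a: (group[a], ranks[a]))
    )
    grow_order: list[int] = []
    while frontier:
        u = frontier.popleft()
        for v in neighbors(u):
            if v not in group:
                group[v] = group[u]
                parent[v] = u
                grow_order.append(v)
                frontier.append(v)

    def atom_token(i):
        a = kek.GetAtomWithIdx(i)
        return vocab.atom_index(a.GetSymbol(), a.GetFormalCharge())

    columns: list[tuple[int, int, int, int, int]] = [(GO_IDX, 0, 0, 0, 0)]
    emit_idx: dict[int, int] = {}
    deferred_links: list[tuple[int, int]] = []
    pending_growing: list[tuple[int, int, int]] = []  # cross-group non-single bonds

    def emit_closures(v, exclude, frag_label, within=None):
        for w in sorted((w for w in neighbors(v) if w in emit_idx), key=emit_idx.get):
            if w == exclude:
                continue
            order = bond_order.get(frozenset((v, w)))
            if order is None:
                continue
            cross = group[v] != group[w]
            if cross and order == 1:
                deferred_links.append((w, v))
            elif cross and within is not None:
                # fragment section may not hold cross-fragment bonds; emit
                # non-single ones at the start of the growing section
                pending_growing.append((order, emit_idx[w], emit_idx[v]))
            else:
                columns.append((0, order, emit_idx[w], emit_idx[v], frag_label))

    # fragment sections
    for gi, match in enumerate(matches, start=1):
        in_frag = set(match)
        start = min(match, key=lambda a: ranks[a])
        order_bfs = [start]
        seen = {start}
        q = deque([start])
        while q:
            u = q.popleft()
            for v in neighbors(u):
                if v in in_frag and v not in seen:
                    seen.add(v)
                    order_bfs.append(v)
                    q.append(v)
        for v in order_bfs:
            placed_nb = [w for w in neighbors(v) if w in emit_idx and w in in_frag]
            idx = len(emit_idx)
            emit_idx[v] = idx
            if not placed_nb:
                columns.append((atom_token(v), 0, idx, idx, gi))
            else:
                u = min(placed_nb, key=emit_idx.get)
                columns.append(
                    (atom_token(v), bond_order[frozenset((u, v))], emit_idx[u], idx, gi)
                )
                emit_closures(v, exclude=u, frag_label=gi, within=in_frag)

    # growing section
    for order, iw, iv in pending_growing:
        columns.append((0, order, iw, iv, 0))
    for v in grow_order:
        u = parent[v]
        idx = len(emit_idx)
        emit_idx[v] = idx
        columns.append(
            (atom_token(v), bond_order[frozenset((u, v))], emit_idx[u], idx, 0)
        )
        emit_closures(v, exclude=u, frag_label=0)

    columns.append((END_IDX, 0, 0, 0, 0))

    # linking section: deferred single bonds between different groups
    for w, v in sorted(deferred_links, key=lambda p: (emit_idx[p[1]], emit_idx[p[0]])):
        columns.append((0, 1, emit_idx[w], emit_idx[v], 0))
    columns.append((END_IDX, 0, 0, 0, 0))

    if len(emit_idx) != kek.GetNumAtoms():
        raise EncodeError("molecule is disconnected from its fragments")
    return GraphMatrix(np.array(columns, dtype=np.int64).T)


# ---------------------------------------------------------------------------
# decoding


def decode_graph(g: GraphMatrix, vocab: GraphVocab | None = None) -> MoleculeRecord:
    """Rebuild the molecule from a graph matrix and sanitize it.

    Aromatic rings are inferred automatically by RDKit sanitization; the
    matrix itself carries only kekulized single/double/triple bonds.
    """
    vocab = vocab or GraphVocab()
    rw = Chem.RWMol()
    n_end = 0
    n_atoms = 0
    for col in range(g.n_columns):
        t_atom, t_bond, i_conn, i_cur, _ = (int(x) for x in g.data[:, col])
        if t_atom == GO_IDX:
            continue
        if t_atom == END_IDX:
            n_end += 1
            if n_end == 2:
                break
            continue
        if t_atom == BLANK_IDX and t_bond == 0:
            continue  # padding
        try:
            if t_atom != BLANK_IDX:
                if i_cur != n_atoms:
                    raise DecodeError(
                        f"new atom index {i_cur} != running count {n_atoms}", col
                    )
                rw.AddAtom(vocab.make_atom(t_atom))
                n_atoms += 1
                if t_bond != 0:
                    rw.AddBond(i_conn, i_cur, BOND_ORDERS[t_bond])
            else:
                if i_conn >= n_atoms or i_cur >= n_atoms or i_conn == i_cur:
                    raise DecodeError(
                        f"bond references missing atoms ({i_conn}, {i_cur})", col
                    )
                rw.AddBond(i_conn, i_cur, BOND_ORDERS[t_bond])
        except DecodeError:
            raise
        except Exception as exc:
            raise DecodeError(str(exc), col) from exc
    if rw.GetNumAtoms() == 0:
        raise DecodeError("matrix decodes to an empty molecule")
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise DecodeError(f"sanitization failed: {exc}") from exc
    return MoleculeRecord(smiles=Chem.MolToSmiles(mol))


# ---------------------------------------------------------------------------
# valence-mask state machine


@dataclass
class MaskSets:
    """Allowed continuations for the next column given a partial matrix."""

    atoms: set[int]
    bonds: dict[int, set[int]]
    connections: dict[tuple[int, int], set[int]]
    currents: dict[tuple[int, int, int], set[int]]


class GraphState:
    """Partial-matrix state used to mask invalid continuations.

    Tracks, per placed atom, the remaining valence and the connected
    component, plus the set of placed bonds.  Phases: ``grow`` (new atoms
    and ring closures), ``link`` (single bonds between components only,
    entered after the first end token), ``done``.
    """

    GROW, LINK, DONE = "grow", "link", "done"

    def __init__(self, vocab: GraphVocab, max_atoms: int):
        self.vocab = vocab
        self.max_atoms = max_atoms
        self.atom_types: list[int] = []
        self.remaining: list[int] = []
        self.comp: list[int] = []
        self.bonds: set[frozenset] = set()
        self.phase = self.GROW
        self.columns: list[tuple[int, int, int, int, int]] = []

    # union-find over components
    def _find(self, i):
        while self.comp[i] != i:
            self.comp[i] = self.comp[self.comp[i]]
            i = self.comp[i]
        return i

    def _union(self, i, j):
        ri, rj = self._find(i), self._find(j)
        if ri != rj:
            self.comp[ri] = rj

    @property
    def n_atoms(self):
        return len(self.atom_types)

    def n_components(self):
        return len({self._find(i) for i in range(self.n_atoms)}) if self.n_atoms else 0

    def apply(self, column, frag_label: int = 0):
        """Advance the state by one (T_atom, T_bond, I_conn, I_cur) column."""
        t_atom, t_bond, i_conn, i_cur = (int(x) for x in column[:4])
        self.columns.append((t_atom, t_bond, i_conn, i_cur, frag_label))
        if t_atom == GO_IDX:
            return
        if t_atom == END_IDX:
            self.phase = self.LINK if self.phase == self.GROW else self.DONE
            return
        if t_atom != BLANK_IDX:
            assert i_cur == self.n_atoms, "new atom must take the next free index"
            self.atom_types.append(t_atom)
            self.remaining.append(int(self.vocab.max_valence[t_atom]))
            self.comp.append(i_cur)
            if t_bond != 0:
                self._add_bond(i_conn, i_cur, t_bond)
        else:
            self._add_bond(i_conn, i_cur, t_bond)

    def _add_bond(self, i, j, order):
        self.remaining[i] -= order
        self.remaining[j] -= order
        assert self.remaining[i] >= 0 and self.remaining[j] >= 0, "valence exceeded"
        self.bonds.add(frozenset((i, j)))
        self._union(i, j)

    # -- mask queries --------------------------------------------------------
    def _rem(self):
        return np.array(self.remaining, dtype=np.int64)

    def _closure_pairs(self, min_order: int = 1, cross_only: bool = False, first_only=False):
        rem = self._rem()
        elig = np.flatnonzero(rem >= min_order)
        pairs = []
        for ai in range(len(elig)):
            for bi in range(ai + 1, len(elig)):
                i, j = int(elig[ai]), int(elig[bi])
                if frozenset((i, j)) in self.bonds:
                    continue
                if cross_only and self._find(i) == self._find(j):
                    continue
                pairs.append((i, j))
                if first_only:
                    return pairs
        return pairs

    def allowed_atoms(self) -> set[int]:
        if self.phase == self.DONE:
            return set()
        rem = self._rem()
        allowed: set[int] = set()
        if self.phase == self.GROW:
            allowed.add(END_IDX)
            if self.n_atoms < self.max_atoms and (rem >= 1).any():
                for t in range(3, len(self.vocab)):
                    if self.vocab.max_valence[t] >= 1:
                        allowed.add(t)
            if self._closure_pairs(1, first_only=True):
                allowed.add(BLANK_IDX)
        else:  # LINK
            cross = self._closure_pairs(1, cross_only=True, first_only=True)
            if cross:
                allowed.add(BLANK_IDX)
            if self.n_components() <= 1 or not cross:
                allowed.add(END_IDX)
        return allowed

    def allowed_bonds(self, t_atom: int) -> set[int]:
        if t_atom == END_IDX:
            return {0}
        rem = self._rem()
        out = set()
        if t_atom == BLANK_IDX:
            if self.phase == self.LINK:
                if self._closure_pairs(1, cross_only=True, first_only=True):
                    out.add(1)
            else:
                for b in (1, 2, 3):
                    if self._closure_pairs(b, first_only=True):
                        out.add(b)
            return out
        cap = int(self.vocab.max_valence[t_atom])
        for b in (1, 2, 3):
            if b <= cap and (rem >= b).any():
                out.add(b)
        return out

    def allowed_connections(self, t_atom: int, t_bond: int) -> set[int]:
        if t_atom == END_IDX:
            return {0}
        rem = self._rem()
        if t_atom == BLANK_IDX:
            cross = self.phase == self.LINK
            pairs = self._closure_pairs(t_bond, cross_only=cross)
            return {i for i, _ in pairs} | {j for _, j in pairs}
        return {int(i) for i in np.flatnonzero(rem >= t_bond)}

    def allowed_currents(self, t_atom: int, t_bond: int, i_conn: int) -> set[int]:
        if t_atom == END_IDX:
            return {0}
        if t_atom != BLANK_IDX:
            return {self.n_atoms}
        rem = self._rem()
        cross = self.phase == self.LINK
        out = set()
        for j in np.flatnonzero(rem >= t_bond):
            j = int(j)
            if j == i_conn or frozenset((i_conn, j)) in self.bonds:
                continue
            if cross and self._find(i_conn) == self._find(j):
                continue
            out.add(j)
        return out


def valence_mask(state: GraphState) -> MaskSets:
    """All valid continuations of a partial matrix, as explicit sets.

    Never empty on a valid prefix: the end token is always permitted while
    growing, and in the linking phase whenever no feasible link remains.
    """
    atoms = state.allowed_atoms()
    bonds = {a: state.allowed_bonds(a) for a in atoms}
    connections = {}
    currents = {}
    for a, bs in bonds.items():
        for b in bs:
            conns = state.allowed_connections(a, b)
            connections[(a, b)] = conns
            for c in conns:
                currents[(a, b, c)] = state.allowed_currents(a, b, c)
    return MaskSets(atoms, bonds, connections, currents)


def state_from_scaffold(
    scaffold: str, vocab: GraphVocab, max_atoms: int
) -> tuple[GraphState, np.ndarray]:
    """Initial generation state: fragment columns applied, phase = grow.

    Returns the state and the encoder columns (GO + fragment sections).
    """
    fragments = scaffold.split(".")
    # Encode the scaffold's own fragments as a standalone "molecule" whose
    # components are exactly the fragments (no growing/linking columns).
    combined = Chem.MolFromSmiles(scaffold)
    if combined is None:
        raise EncodeError(f"unparsable scaffold {scaffold!r}")
    rec = MoleculeRecord(smiles=scaffold)
    matrix = encode_graph(rec, fragments, vocab)
    enc_cols, _ = matrix.split_sections()
    state = GraphState(vocab, max_atoms)
    for col in range(enc_cols.shape[1]):
        t_atom = int(enc_cols[0, col])
        if t_atom == GO_IDX:
            continue
        state.apply(enc_cols[:4, col], frag_label=int(enc_cols[4, col]))
    return state, enc_cols
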