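"""Pedigree validation and the numerator relationship matrix.

The numerator relationship matrix ``A`` holds expected additive-genetic
relationships between animals: ``a_ij`` is twice the kinship coefficient, and
``a_ii = 1 + F_i`` where ``F_i`` is the animal's inbreeding coefficient.  ``A``
is built with the tabular method, which recurses over a topologically sorted
pedigree:

* ``a_ii = 1 + 0.5 * a_{sire,dam}`` (0 if either parent is unknown),
* ``a_ij = 0.5 * (a_{j,sire(i)} + a_{j,dam(i)})`` for ``j`` earlier than ``i``.

Unknown parents are treated as unrelated, non-inbred founders (no genetic
groups).  A dense matrix is used throughout: the package targets desk-scale
pedigrees (thousands of animals), where dense ``A`` plus one Cholesky or
eigendecomposition is simpler and fast enough.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = "0"
#: Tokens accepted as "parent unknown" in pedigree files.
_MISSING_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "unknown", "UNKNOWN"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate ids, self-parenting, cycles)."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    animal_ids : list of str
        Animal identifiers, parents always before offspring.
    sire_ids, dam_ids : list of str
        Parent identifiers; :data:`UNKNOWN` ("0") marks a missing parent.
    generation : list of int
        Generation number per animal (founders = 0); for pedigrees read from
        file this is the longest ancestral path to a founder.
    """

    animal_ids: list[str]
    sire_ids: list[str]
    dam_ids: list[str]
    generation: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (len(self.animal_ids) == len(self.sire_ids) == len(self.dam_ids)):
            raise PedigreeError("animal/sire/dam id lists must have equal length")
        if not self.generation:
            self.generation = _generations(self.animal_ids, self.sire_ids, self.dam_ids)

    def __len__(self) -> int:
        return len(self.animal_ids)

    @property
    def index(self) -> dict[str, int]:
        """Mapping animal id -> row position."""
        return {a: i for i, a in enumerate(self.animal_ids)}

    def parent_indices(self) -> np.ndarray:
        """(n, 2) integer array of sire/dam row positions, -1 for unknown."""
        idx = self.index
        out = np.full((len(self), 2), -1, dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.sire_ids, self.dam_ids)):
            if s != UNKNOWN:
                out[i, 0] = idx[s]
            if d != UNKNOWN:
                out[i, 1] = idx[d]
        return out

    def is_founder(self) -> np.ndarray:
        """Boolean vector: both parents unknown."""
        return np.array(
            [s == UNKNOWN and d == UNKNOWN for s, d in zip(self.sire_ids, self.dam_ids)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_ids,
                "sire_id": self.sire_ids,
                "dam_id": self.dam_ids,
                "generation": self.generation,
            }
        )

    def to_csv(self, path) -> None:
        """Write animal_id,sire_id,dam_id (unknown parent written as 0)."""
        self.to_frame()[["animal_id", "sire_id", "dam_id"]].to_csv(path, index=False)


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix with its id ordering.

    ``inbreeding`` is ``diag(A) - 1``; founders have diagonal exactly 1.
    """

    A: np.ndarray
    animal_ids: list[str]

    @property
    def animal_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.A) - 1.0

    def submatrix(self, ids: list[str]) -> "RelationshipMatrix":
        """A restricted to (and ordered by) ``ids``."""
        idx = self.animal_index
        rows = np.array([idx[a] for a in ids])
        return RelationshipMatrix(self.A[np.ix_(rows, rows)], list(ids))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.A, index=self.animal_ids, columns=self.animal_ids).to_csv(path)


def _normalize_parent(token) -> str:
    token = "" if token is None or (isinstance(token, float) and np.isnan(token)) else str(token)
    return UNKNOWN if token.strip() in _MISSING_TOKENS else token.strip()


def _generations(animals, sires, dams) -> list[int]:
    pos = {a: i for i, a in enumerate(animals)}
    gen = [0] * len(animals)
    for i, (s, d) in enumerate(zip(sires, dams)):
        g = 0
        for p in (s, d):
            if p != UNKNOWN:
                g = max(g, gen[pos[p]] + 1)
        gen[i] = g
    return gen


def validate_pedigree(records) -> Pedigree:
    """Validate and topologically sort raw (animal, sire, dam) triplets.

    Parameters
    ----------
    records : iterable of (animal_id, sire_id, dam_id)
        Any parent token in ``{"", "0", "NA", ...}`` is treated as unknown.
        Parents that never appear as animals are added as founders.

    Returns
    -------
    Pedigree
        Sorted so every known parent precedes its offspring.

    Raises
    ------
    PedigreeError
        On duplicate animal ids, an animal listed as its own parent, or a
        pedigree cycle (the error message names the cycle members).
    """
    triplets = [(str(a).strip(), _normalize_parent(s), _normalize_parent(d)) for a, s, d in records]
    seen: set[str] = set()
    for a, s, d in triplets:
        if a in _MISSING_TOKENS:
            raise PedigreeError(f"invalid animal id {a!r}")
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r}")
        seen.add(a)
        if a == s or a == d:
            raise PedigreeError(f"animal {a!r} listed as its own parent")

    parents: dict[str, tuple[str, str]] = {a: (s, d) for a, s, d in triplets}
    # phantom parents become founders
    for a, s, d in triplets:
        for p in (s, d):
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)

    # Kahn's algorithm, stable in the input order; leftovers sit on a cycle.
    import heapq

    pos = {a: i for i, a in enumerate(parents)}
    order: list[str] = []
    n_known = {
        a: sum(p != UNKNOWN for p in ps) for a, ps in parents.items()
    }
    children: dict[str, list[str]] = {a: [] for a in parents}
    for a, (s, d) in parents.items():
        for p in {s, d} - {UNKNOWN}:
            children[p].append(a)
    ready = [(pos[a], a) for a, k in n_known.items() if k == 0]
    heapq.heapify(ready)
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            # one edge per distinct parent; a repeated parent clears both slots
            n_known[c] -= 1 if parents[c][0] != parents[c][1] else 2
            if n_known[c] == 0:
                heapq.heappush(ready, (pos[c], c))
    if len(order) < len(parents):
        cycle = sorted(set(parents) - set(order))
        raise PedigreeError(f"pedigree cycle involving: {', '.join(cycle)}")

    sires = [parents[a][0] for a in order]
    dams = [parents[a][1] for a in order]
    return Pedigree(order, sires, dams)


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    The pedigree must be (or will be re-)topologically sorted.  Runs the
    classic recursion in O(n^2) with vectorized row updates.
    """
    ped = pedigree
    par = ped.parent_indices()
    if np.any(par >= np.arange(len(ped))[:, None]):
        ped = validate_pedigree(list(zip(ped.animal_ids, ped.sire_ids, ped.dam_ids)))
        par = ped.parent_indices()
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return RelationshipMatrix(A, list(ped.animal_ids))


def read_pedigree_csv(path) -> Pedigree:
    """Read the pedigree CSV dialect: header ``animal_id,sire_id,dam_id``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"animal_id", "sire_id", "dam_id"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree CSV needs columns {sorted(required)}")
    return validate_pedigree(df[["animal_id", "sire_id", "dam_id"]].itertuples(index=False))
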