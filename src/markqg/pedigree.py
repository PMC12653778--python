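"""Pedigree ingestion and relationship algebra.

A pedigree is the directed acyclic graph of parent-offspring links.  From it
we derive the quantities every animal-model analysis needs:

* inbreeding coefficients ``F`` (Meuwissen & Luo ancestor tracing),
* the numerator relationship matrix ``A`` with diagonal ``1 + F`` (dense
  tabular method, for small/medium pedigrees),
* the sparse inverse ``A^-1`` assembled directly from pedigree structure
  (Henderson's rules with the Quaas inbreeding adjustment), which is what
  mixed-model equations actually embed.

Animal identifiers are opaque strings; ``""`` and ``"0"`` both denote an
unknown parent.  Internally animals are coded 0..n-1 in an order where every
parent precedes its offspring; ``-1`` codes an unknown parent.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = -1

_MISSING_TOKENS = {"", "0", "NA", "na", "nan", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids, ...)."""


@dataclass
class Pedigree:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    ids : list[str]
        Animal identifiers in internal order (parents precede offspring).
    sire, dam : ndarray of int
        Internal parent codes per animal; ``-1`` means unknown.
    birth_year : ndarray or None
        Optional integer birth years aligned with ``ids``.
    sex : ndarray or None
        Optional per-animal sex labels aligned with ``ids``.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray | None = None
    sex: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        for k in range(self.n):
            for p in (self.sire[k], self.dam[k]):
                if p != UNKNOWN and p >= k:
                    raise PedigreeError(
                        f"pedigree not ordered: parent of {self.ids[k]!r} follows it"
                    )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def is_founder(self, i: int) -> bool:
        return self.sire[i] == UNKNOWN and self.dam[i] == UNKNOWN

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    # -- construction ---------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, *, add_missing_parents: bool = True) -> "Pedigree":
        """Build an ordered pedigree from a DataFrame with columns
        ``animal, sire, dam`` (optionally ``birth_year``, ``sex``).

        Parents referenced but never listed as animals are auto-inserted as
        founders when ``add_missing_parents`` is true, otherwise an error is
        raised.  Rows may be in any order; a Kahn topological sort with
        input-order tie-breaking produces a deterministic internal order.
        """
        animals = [str(a).strip() for a in frame["animal"]]
        if len(set(animals)) != len(animals):
            dupes = pd.Series(animals)
            dup = dupes[dupes.duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup!r}")

        def norm(v) -> str | None:
            s = "" if v is None or (isinstance(v, float) and np.isnan(v)) else str(v).strip()
            return None if s in _MISSING_TOKENS else s

        sires = [norm(v) for v in frame["sire"]]
        dams = [norm(v) for v in frame["dam"]]

        known = set(animals)
        referenced = [p for p in sires + dams if p is not None and p not in known]
        order_seen: list[str] = []
        seen: set[str] = set()
        for p in referenced:
            if p not in seen:
                seen.add(p)
                order_seen.append(p)
        if order_seen and not add_missing_parents:
            raise PedigreeError(f"parent {order_seen[0]!r} referenced but never defined")

        all_ids = order_seen + animals  # phantom founders first
        parent_map: dict[str, tuple[str | None, str | None]] = {p: (None, None) for p in order_seen}
        for a, s, d in zip(animals, sires, dams):
            parent_map[a] = (s, d)

        order = _topological_order(all_ids, parent_map)
        idx = {a: i for i, a in enumerate(order)}

        def code(p: str | None) -> int:
            return UNKNOWN if p is None else idx[p]

        sire_arr = np.array([code(parent_map[a][0]) for a in order], dtype=np.int64)
        dam_arr = np.array([code(parent_map[a][1]) for a in order], dtype=np.int64)

        by = sx = None
        if "birth_year" in frame.columns:
            src = dict(zip(animals, frame["birth_year"]))
            by = np.array(
                [int(src[a]) if a in src and pd.notna(src[a]) else -1 for a in order],
                dtype=np.int64,
            )
        if "sex" in frame.columns:
            src = dict(zip(animals, frame["sex"].astype(str)))
            sx = np.array([src.get(a, "") for a in order], dtype=object)

        return cls(ids=order, sire=sire_arr, dam=dam_arr, birth_year=by, sex=sx)

    def to_frame(self) -> pd.DataFrame:
        def label(p: int) -> str:
            return "" if p == UNKNOWN else self.ids[p]

        out = pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [label(s) for s in self.sire],
                "dam": [label(d) for d in self.dam],
            }
        )
        if self.birth_year is not None:
            out["birth_year"] = self.birth_year
        if self.sex is not None:
            out["sex"] = self.sex
        return out


def _topological_order(ids: list[str], parents: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Kahn topological sort, breaking ties by input order (deterministic)."""
    pos = {a: i for i, a in enumerate(ids)}
    children: dict[str, list[str]] = {a: [] for a in ids}
    indeg = {a: 0 for a in ids}
    for a, (s, d) in parents.items():
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                indeg[a] += 1
    ready = deque(sorted((a for a in ids if indeg[a] == 0), key=pos.__getitem__))
    order: list[str] = []
    while ready:
        a = ready.popleft()
        order.append(a)
        emitted = []
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                emitted.append(c)
        for c in sorted(emitted, key=pos.__getitem__):
            ready.append(c)
    if len(order) != len(ids):
        stuck = next(a for a in ids if indeg[a] > 0)
        raise PedigreeError(f"cycle detected in pedigree involving animal {stuck!r}")
    return order


def load_pedigree(path, *, add_missing_parents: bool = True) -> Pedigree:
    """Read a pedigree CSV/TSV with header ``animal,sire,dam[,birth_year][,sex]``.

    The delimiter (comma or tab) is autodetected; unknown parents are coded
    as an empty field or ``"0"``.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    frame.columns = [c.strip().lower() for c in frame.columns]
    required = {"animal", "sire", "dam"}
    if not required.issubset(frame.columns):
        raise PedigreeError(f"pedigree file must have columns {sorted(required)}")
    return Pedigree.from_frame(frame, add_missing_parents=add_missing_parents)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


# -- inbreeding and relationship matrices -------------------------------


def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients by Meuwissen & Luo ancestor tracing.

    Exact and O(n * pedigree depth); founders get F = 0, and F_i equals half
    the additive relationship of i's parents.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    # L[j]: coefficient relating animal i's breeding value to ancestor j's
    # Mendelian sampling term; D[j]: within-family variance of j.
    L = np.zeros(n)
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        Fs = F[s] if s != UNKNOWN else 0.0
        Fd = F[d] if d != UNKNOWN else 0.0
        n_known = int(s != UNKNOWN) + int(d != UNKNOWN)
        D[i] = 0.5 - 0.25 * (Fs + Fd) + 0.25 * (2 - n_known)
        if s == UNKNOWN or d == UNKNOWN:
            F[i] = 0.0
            continue
        # trace ancestors of i, youngest first so each L[j] is complete
        # (parents always have smaller internal indices than offspring)
        L[i] = 1.0
        heap = [-i]
        active = [i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L[j]
            if lj == 0.0:  # duplicate heap entry already processed
                continue
            sj, dj = sire[j], dam[j]
            if sj != UNKNOWN:
                if L[sj] == 0.0:
                    heapq.heappush(heap, -sj)
                    active.append(sj)
                L[sj] += 0.5 * lj
            if dj != UNKNOWN and dj != sj:
                if L[dj] == 0.0:
                    heapq.heappush(heap, -dj)
                    active.append(dj)
                L[dj] += 0.5 * lj
            elif dj != UNKNOWN:  # selfed parent: both links go to the same j
                L[dj] += 0.5 * lj
            a_ii += lj * lj * D[j]
            L[j] = 0.0
        F[i] = a_ii - 1.0
        for j in active:  # clear any leftovers (founders keep L until popped)
            L[j] = 0.0
    return F


def relationship_matrix(ped: Pedigree, *, max_animals: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    Refuses pedigrees larger than ``max_animals`` (quadratic memory); use
    :func:`a_inverse` for the sparse inverse needed by samplers.
    """
    n = ped.n
    if n > max_animals:
        raise PedigreeError(
            f"pedigree of {n} animals exceeds dense limit {max_animals}; "
            "raise max_animals explicitly if this is intentional"
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(n)
        if s != UNKNOWN:
            row += 0.5 * A[s]
        if d != UNKNOWN:
            row += 0.5 * A[d]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
    return A


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family (Mendelian sampling) variance d_i for every animal.

    d = 0.5 - 0.25 (F_s + F_d) with both parents known; an unknown parent
    contributes F = 0 and adds 0.25 to d (so 0.75 with one parent known,
    1.0 with none) — the standard Quaas convention for unknown parents
    treated as unique unrelated founders.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    s_known = ped.sire != UNKNOWN
    d_known = ped.dam != UNKNOWN
    Fs = np.where(s_known, F[np.where(s_known, ped.sire, 0)], 0.0)
    Fd = np.where(d_known, F[np.where(d_known, ped.dam, 0)], 0.0)
    n_unknown = 2 - (s_known.astype(int) + d_known.astype(int))
    return 0.5 - 0.25 * (Fs + Fd) + 0.25 * n_unknown


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A^-1 assembled from pedigree structure without forming A.

    Henderson's rules: each animal contributes 1/d_i to the 3x3 block over
    (animal, sire, dam) with weights (1, -0.5, -0.5), where d_i is the
    Mendelian sampling variance adjusted for parental inbreeding.
    """
    if F is None:
        F = inbreeding_coefficients(ped)
    d = mendelian_sampling_variance(ped, F)
    n = ped.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    idx = np.arange(n)
    w = 1.0 / d
    # animal-animal
    rows.append(idx)
    cols.append(idx)
    vals.append(w)
    for parent in (ped.sire, ped.dam):
        known = parent != UNKNOWN
        p = parent[known]
        a = idx[known]
        rows.append(a)
        cols.append(p)
        vals.append(-0.5 * w[known])
        rows.append(p)
        cols.append(a)
        vals.append(-0.5 * w[known])
        rows.append(p)
        cols.append(p)
        vals.append(0.25 * w[known])
    # sire-dam cross terms where both known
    both = (ped.sire != UNKNOWN) & (ped.dam != UNKNOWN)
    s, dd = ped.sire[both], ped.dam[both]
    rows.append(s)
    cols.append(dd)
    vals.append(0.25 * w[both])
    rows.append(dd)
    cols.append(s)
    vals.append(0.25 * w[both])

    Ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return Ainv.tocsr()
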