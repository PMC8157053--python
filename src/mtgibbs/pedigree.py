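"""Pedigree handling and additive-relationship algebra.

A pedigree is a list of (animal, sire, dam) triplets.  After validation the
animals are renumbered with consecutive integer codes in a topological order
(parents before offspring), which is what every downstream recursion assumes.
The module computes inbreeding coefficients F, the numerator relationship
matrix A (tabular method, dense, for small pedigrees only) and the sparse
inverse of A directly from the pedigree via Henderson's rules with the
Meuwissen & Luo inbreeding recursion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "RelationshipStructure",
    "load_pedigree",
    "write_pedigree",
    "compute_inbreeding",
    "build_A_dense",
    "build_A_inverse",
    "build_relationship",
]

#: Internal integer code for an unknown parent.
UNKNOWN = -1

#: Tokens accepted as "parent unknown" on input (configurable in loaders).
DEFAULT_UNKNOWN_TOKENS = ("", "0", "NA")

#: build_A_dense refuses above this size; the pipeline proper only needs A^-1.
DENSE_GUARD = 2000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    Attributes
    ----------
    labels : list of str
        Original animal labels, indexed by internal code. Parents always
        carry a smaller code than their offspring.
    sire, dam : ndarray of int
        Parent codes per animal; ``UNKNOWN`` (-1) marks a missing parent.
    order_index : dict
        Mapping label -> internal code.
    """

    labels: list[str]
    sire: np.ndarray
    dam: np.ndarray
    order_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.order_index:
            self.order_index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_animals(self) -> int:
        return len(self.labels)

    def is_founder(self, code: int) -> bool:
        return self.sire[code] == UNKNOWN and self.dam[code] == UNKNOWN

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def codes_of(self, labels) -> np.ndarray:
        """Translate labels to internal codes, raising on unknown labels."""
        try:
            return np.array([self.order_index[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None


@dataclass
class RelationshipStructure:
    """Inbreeding, (optionally) dense A and the sparse A-inverse of a pedigree."""

    inbreeding: np.ndarray
    A_inverse: sparse.csr_matrix
    A: np.ndarray | None = None


def _normalize_parent(token, unknown_tokens) -> str | None:
    if token is None:
        return None
    tok = str(token).strip()
    if tok in unknown_tokens or tok.lower() == "nan":
        return None
    return tok


def from_records(
    records: list[tuple[str, str | None, str | None]],
) -> Pedigree:
    """Build an ordered pedigree from (animal, sire, dam) label triplets.

    Parents that never appear as animals are prepended as founders.  The
    ordering is a topological sort that is deterministic: ties are broken by
    the position of the animal in the input (implied founders first, in order
    of first mention).
    """
    seen: dict[str, int] = {}
    for animal, _, _ in records:
        if animal in seen:
            raise PedigreeError(f"duplicate pedigree entry for animal {animal!r}")
        seen[animal] = len(seen)

    # implied founders: labels used only as parents
    implied: list[str] = []
    implied_set: set[str] = set()
    for _, s, d in records:
        for p in (s, d):
            if p is not None and p not in seen and p not in implied_set:
                implied.append(p)
                implied_set.add(p)

    all_records: list[tuple[str, str | None, str | None]] = [
        (lab, None, None) for lab in implied
    ] + list(records)
    parent_of = {a: (s, d) for a, s, d in all_records}
    input_pos = {a: i for i, (a, _, _) in enumerate(all_records)}

    # Kahn-style topological sort, stable in input order.
    n = len(all_records)
    indeg = {a: 0 for a in parent_of}
    children: dict[str, list[str]] = {a: [] for a in parent_of}
    for a, (s, d) in parent_of.items():
        for p in {p for p in (s, d) if p is not None}:
            indeg[a] += 1
            children[p].append(a)
    import heapq

    ready = [(input_pos[a], a) for a, k in indeg.items() if k == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (input_pos[c], c))
    if len(order) != n:
        stuck = next(a for a, k in indeg.items() if k > 0)
        raise PedigreeError(
            f"pedigree contains a cycle involving animal {stuck!r} "
            "(an animal is its own ancestor)"
        )

    code = {a: i for i, a in enumerate(order)}
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    for a, (s, d) in parent_of.items():
        i = code[a]
        if s is not None:
            sire[i] = code[s]
        if d is not None:
            dam[i] = code[d]
    return Pedigree(labels=order, sire=sire, dam=dam, order_index=code)


def load_pedigree(
    path,
    animal_col: str = "animal",
    sire_col: str = "sire",
    dam_col: str = "dam",
    sep: str | None = None,
    unknown_tokens=DEFAULT_UNKNOWN_TOKENS,
) -> Pedigree:
    """Read a delimited pedigree file and return a validated :class:`Pedigree`.

    ``sep=None`` sniffs comma vs tab from the header line.  Unknown parents
    may be encoded by any of ``unknown_tokens`` (default: empty, "0", "NA").
    Animals referenced only as parents are appended as founders.
    """
    path = Path(path)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (animal_col, sire_col, dam_col):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file {path} lacks column {col!r}")
    records = [
        (
            str(row[animal_col]).strip(),
            _normalize_parent(row[sire_col], unknown_tokens),
            _normalize_parent(row[dam_col], unknown_tokens),
        )
        for _, row in df.iterrows()
    ]
    return from_records(records)


def write_pedigree(ped: Pedigree, path, mapping_path=None, sep: str = ",") -> None:
    """Write the renumbered pedigree; original labels go to ``mapping_path``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(["animal", "sire", "dam"])
        for i in range(len(ped)):
            s = ped.labels[ped.sire[i]] if ped.sire[i] != UNKNOWN else "0"
            d = ped.labels[ped.dam[i]] if ped.dam[i] != UNKNOWN else "0"
            w.writerow([ped.labels[i], s, d])
    if mapping_path is not None:
        with open(mapping_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=sep)
            w.writerow(["code", "label"])
            for i, lab in enumerate(ped.labels):
                w.writerow([i, lab])


def compute_inbreeding(ped: Pedigree, use_inbreeding: bool = True) -> np.ndarray:
    """Inbreeding coefficients F via the Meuwissen & Luo recursion.

    F[i] is half the additive relationship between i's parents; animals with
    an unknown parent get F = 0.  ``use_inbreeding=False`` returns zeros,
    matching software that builds A^-1 ignoring inbreeding (comparison flag).
    """
    n = len(ped)
    if not use_inbreeding or n == 0:
        return np.zeros(n)
    import heapq

    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            continue  # F = 0 by the base-population convention
        # Evaluate a(i,i) = 1 + F_i on the animal itself: decompose u_i over
        # its ancestors j with coefficients L[j]; then a(i,i) = sum L_j^2 D_j
        # where D_j is the Mendelian-sampling variance ratio of j.  Ancestors
        # are processed in decreasing code order (parents have smaller codes)
        # so each L[j] is final when popped.
        L: dict[int, float] = {i: 1.0}
        heap = [-i]
        fi = -1.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            sj, dj = sire[j], dam[j]
            if sj != UNKNOWN and dj != UNKNOWN:
                Dj = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj != UNKNOWN or dj != UNKNOWN:
                Dj = 0.75 - 0.25 * F[sj if sj != UNKNOWN else dj]
            else:
                Dj = 1.0
            fi += lj * lj * Dj
            for p in (sj, dj):
                if p == UNKNOWN:
                    continue
                if p in L:
                    L[p] += 0.5 * lj
                else:
                    L[p] = 0.5 * lj
                    heapq.heappush(heap, -p)
        F[i] = fi
    return F


def build_A_dense(ped: Pedigree, guard: int = DENSE_GUARD) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method (dense).

    Intended as an oracle and for small pedigrees; refuses above ``guard``
    animals because the pipeline itself only ever needs the sparse inverse.
    """
    n = len(ped)
    if n > guard:
        raise PedigreeError(
            f"pedigree has {n} animals; build_A_dense is limited to {guard}. "
            "Use build_A_inverse for the model (A itself is never needed)."
        )
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        a_sd = A[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        for j in range(i):
            aij = 0.0
            if s != UNKNOWN:
                aij += 0.5 * A[j, s]
            if d != UNKNOWN:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    return A


def build_A_inverse(
    ped: Pedigree, F: np.ndarray | None = None, use_inbreeding: bool = True
) -> sparse.csr_matrix:
    """Sparse inverse of A straight from the pedigree (Henderson's rules).

    For animal i with parents s, d the Mendelian-sampling variance is
    d_i = 0.5 - 0.25 (F_s + F_d), with an unknown parent's term replaced by
    the base-population convention (0.75 - 0.25 F_p for one known parent,
    1 for none).  alpha_i = 1/d_i is added at (i,i), -alpha/2 at (i,parent)
    and alpha/4 between known parents.
    """
    n = len(ped)
    if F is None:
        F = compute_inbreeding(ped, use_inbreeding=use_inbreeding)
    if len(F) != n:
        raise PedigreeError(
            f"inbreeding vector length {len(F)} does not match pedigree size {n}"
        )
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        known = [p for p in (s, d) if p != UNKNOWN]
        if len(known) == 2:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif len(known) == 1:
            di = 0.75 - 0.25 * F[known[0]]
        else:
            di = 1.0
        alpha = 1.0 / di
        add(i, i, alpha)
        for p in known:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in known:
            for q in known:
                add(p, q, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def build_relationship(
    ped: Pedigree, dense: bool = False, use_inbreeding: bool = True
) -> RelationshipStructure:
    """Convenience wrapper bundling F, A^-1 and (optionally) dense A."""
    F = compute_inbreeding(ped, use_inbreeding=use_inbreeding)
    Ainv = build_A_inverse(ped, F, use_inbreeding=use_inbreeding)
    A = build_A_dense(ped) if dense else None
    return RelationshipStructure(inbreeding=F, A_inverse=Ainv, A=A)
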