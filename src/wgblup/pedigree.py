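"""Pedigree parsing/validation and the numerator relationship matrix A.

The A matrix is built by the tabular method; inbreeding coefficients come from
a Meuwissen & Luo style recursion that never materializes the full matrix, and
the two must agree on the diagonal (A_ii = 1 + F_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1  # positional code for an unknown parent


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Topologically sorted pedigree: parents always precede their offspring.

    ``records`` needs columns animal/sire/dam (ids as strings, unknown parents
    as ``None``); birth_date, sex and generation columns are carried along when
    present.  Construction validates id uniqueness and acyclicity and reorders
    records so that every parent precedes its offspring.
    """

    records: pd.DataFrame
    index: dict[str, int] = field(init=False, repr=False)
    sire_idx: np.ndarray = field(init=False, repr=False)
    dam_idx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.records.copy().reset_index(drop=True)
        for col in ("animal", "sire", "dam"):
            if col not in df.columns:
                raise PedigreeError(f"pedigree is missing required column '{col}'")
            df[col] = _normalize_ids(df[col])
        if df["animal"].isna().any():
            raise PedigreeError("missing animal id")
        dup = df["animal"].duplicated()
        if dup.any():
            raise PedigreeError(f"duplicate animal ids: {df.loc[dup, 'animal'].tolist()}")
        self_par = (df["animal"] == df["sire"]) | (df["animal"] == df["dam"])
        if self_par.any():
            raise PedigreeError(
                f"animal listed as its own parent: {df.loc[self_par, 'animal'].tolist()}"
            )
        df = _toposort(df)
        self.records = df
        self.index = {a: i for i, a in enumerate(df["animal"])}
        self.sire_idx = np.array(
            [self.index.get(s, UNKNOWN) if s is not None else UNKNOWN for s in df["sire"]],
            dtype=int,
        )
        self.dam_idx = np.array(
            [self.index.get(d, UNKNOWN) if d is not None else UNKNOWN for d in df["dam"]],
            dtype=int,
        )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return self.records["animal"].tolist()

    def is_founder(self) -> np.ndarray:
        return (self.sire_idx == UNKNOWN) & (self.dam_idx == UNKNOWN)

    def parent_pairs(self) -> list[tuple[str, str]]:
        """All (parent, progeny) id pairs with the parent known."""
        out = []
        for i, (s, d) in enumerate(zip(self.sire_idx, self.dam_idx)):
            child = self.records["animal"].iloc[i]
            if s != UNKNOWN:
                out.append((self.records["animal"].iloc[s], child))
            if d != UNKNOWN:
                out.append((self.records["animal"].iloc[d], child))
        return out

    def write_csv(self, path) -> None:
        df = self.records.copy()
        for col in ("sire", "dam"):
            df[col] = df[col].map(lambda v: "0" if v is None else v)
        df.to_csv(path, index=False)


@dataclass
class AMatrix:
    """Dense numerator relationship matrix over pedigree order."""

    values: np.ndarray
    ids: list[str]

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def write_lower_triangle(self, path) -> None:
        """Whitespace 'i j a_ij' lower triangle with a #id header line."""
        with open(path, "w") as fh:
            fh.write("# " + " ".join(self.ids) + "\n")
            n = self.values.shape[0]
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i + 1} {j + 1} {self.values[i, j]:.10g}\n")


def _normalize_ids(col: pd.Series) -> pd.Series:
    """Ids to str; 0/''/NaN become None (unknown)."""

    def norm(v):
        if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
            return None
        s = str(v).strip()
        if s in ("", "0", "0.0", ".", "NA"):
            return None
        # integer-looking floats from pandas ("123.0")
        if s.endswith(".0") and s[:-2].isdigit():
            s = s[:-2]
        return s

    return col.map(norm)


def _toposort(df: pd.DataFrame) -> pd.DataFrame:
    """Kahn's algorithm over parent->child edges; raises on cycles."""
    ids = df["animal"].tolist()
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p is not None:
                j = pos.get(p)
                if j is None:
                    raise PedigreeError(f"parent '{p}' of '{ids[i]}' not in pedigree")
                children[j].append(i)
                indeg[i] += 1
    order: list[int] = []
    stack = [i for i in range(n) if indeg[i] == 0]
    # stable: process in original order so already-sorted input is unchanged
    stack.sort(reverse=True)
    while stack:
        i = stack.pop()
        order.append(i)
        newly = []
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                newly.append(c)
        newly.sort(reverse=True)
        stack.extend(newly)
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
    return df.iloc[order].reset_index(drop=True)


def read_pedigree(path, **read_csv_kwargs) -> Pedigree:
    """Read a headered CSV with animal/sire/dam (+ optional birth_date, sex).

    Unknown parents may be coded 0 or left empty.  Parents that appear only in
    the sire/dam columns are auto-added as founders (with a warning), matching
    the common situation of a pedigree deeper than the phenotyped set.  The
    returned pedigree carries a ``load_report`` attribute summarising added and
    reordered records.
    """
    df = pd.read_csv(path, dtype=str, **read_csv_kwargs)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("animal", "sire", "dam"):
        df[col] = _normalize_ids(df[col])
    known = set(df["animal"].dropna())
    missing_parents: list[str] = []
    for col in ("sire", "dam"):
        for p in df[col]:
            if p is not None and p not in known and p not in missing_parents:
                missing_parents.append(p)
    if missing_parents:
        warnings.warn(
            f"{len(missing_parents)} parents absent from the animal column; "
            "added as founders",
            stacklevel=2,
        )
        add = pd.DataFrame({"animal": missing_parents})
        for col in df.columns:
            if col not in add.columns:
                add[col] = None
        df = pd.concat([add[df.columns], df], ignore_index=True)
    if "birth_date" in df.columns:
        df["birth_date"] = pd.to_datetime(df["birth_date"])
    ped = Pedigree(df)
    reordered = int((np.array(ped.ids) != np.array(df["animal"])).sum())
    ped.load_report = {  # type: ignore[attr-defined]
        "n_records": ped.n,
        "n_added_founders": len(missing_parents),
        "n_reordered": reordered,
    }
    return ped


def build_A(pedigree: Pedigree) -> AMatrix:
    """Numerator relationship matrix by the tabular method.

    A_ii = 1 + 0.5 A_sd (0 when either parent is unknown);
    A_ij = 0.5 (A_js + A_jd) for j earlier than i, missing parents dropping out.
    """
    n = pedigree.n
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        row = np.zeros(i)
        if s[i] != UNKNOWN:
            row += 0.5 * A[s[i], :i]
        if d[i] != UNKNOWN:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        if s[i] != UNKNOWN and d[i] != UNKNOWN:
            A[i, i] = 1.0 + 0.5 * A[s[i], d[i]]
        else:
            A[i, i] = 1.0
    return AMatrix(A, pedigree.ids)


def inbreeding(pedigree: Pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F_i = A_ii - 1.

    Meuwissen & Luo style recursion: for each animal the relevant row of the
    Cholesky factor L of A is traced back through the ancestors, so the full
    dense A is never stored.
    """
    n = pedigree.n
    s, d = pedigree.sire_idx, pedigree.dam_idx
    F = np.zeros(n)
    # within-family (Mendelian sampling) variances, filled lazily
    for i in range(n):
        if s[i] == UNKNOWN and d[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # trace ancestors of i, accumulating L coefficients
        L: dict[int, float] = {i: 1.0}
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L.pop(j, 0.0)
            if lj == 0.0:
                continue
            fs = F[s[j]] if s[j] != UNKNOWN else -1.0
            fd = F[d[j]] if d[j] != UNKNOWN else -1.0
            # Mendelian sampling variance D_jj
            djj = 0.5 - 0.25 * (fs + fd)
            aii += lj * lj * djj
            if s[j] != UNKNOWN:
                L[s[j]] = L.get(s[j], 0.0) + 0.5 * lj
            if d[j] != UNKNOWN:
                L[d[j]] = L.get(d[j], 0.0) + 0.5 * lj
        F[i] = aii - 1.0
    return F
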