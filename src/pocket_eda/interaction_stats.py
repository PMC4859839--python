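"""Rank correlations and covalency classification of interaction-energy
component tables.

Spearman's rho is computed with the plain rank-difference formula

    rho = 1 - 6 * sum(d_i^2) / (n (n^2 - 1))

with no tie correction (energy components are continuous, ties are
pathological and only raise a warning).  Hydrogen bonds whose
delocalization-to-electrostatics ratio dE_del(HF)/eps_el(10) exceeds 0.45
are classified as partially covalent, following the covalency criterion
for short, charge-transfer-dominated hydrogen bonds.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

COMPONENTS = ["e_hl", "e_el_10", "e_ex_hl", "e_del_hf", "e_hf"]
# external CSV header dialect (reference-table column names)
_CSV_COLUMNS = {"DE_HL": "e_hl", "e_el_10": "e_el_10", "DE_ex_HL": "e_ex_hl",
                "DE_del_HF": "e_del_hf", "DE_HF": "e_hf"}
COVALENCY_THRESHOLD = 0.45
PARTIALLY_COVALENT = "partially-covalent"
ELECTROSTATIC = "electrostatic"

# Donor-H...acceptor contact distances (Å) of the pocket's key hydrogen
# bonds in the representative frame, keyed like the reference table rows.
REFERENCE_HBOND_DISTANCES = {
    "ILE117": 2.03, "ALY16B": 1.93, "ASN248": 2.06, "SER270": 2.13,
    "LEU249": 1.94, "THR37": 1.82, "ALA33": 2.01, "SER225": 2.07,
}


class StatsInputError(ValueError):
    pass


class TieWarning(UserWarning):
    pass


@dataclass
class ComponentTable:
    """Labelled rows of the five interaction-energy quantities, kcal/mol."""

    frame: pd.DataFrame
    additivity_tol: float = 0.05    # kcal/mol, for externally rounded tables

    def __post_init__(self):
        missing = [c for c in ["label", *COMPONENTS]
                   if c not in self.frame.columns]
        if missing:
            raise StatsInputError(f"missing columns: {missing}")
        if self.frame["label"].duplicated().any():
            raise StatsInputError("duplicate row labels")
        resid = (self.frame["e_el_10"] + self.frame["e_ex_hl"]
                 + self.frame["e_del_hf"] - self.frame["e_hf"]).abs()
        bad = self.frame["label"][resid > self.additivity_tol]
        if len(bad):
            warnings.warn(
                f"component sum deviates from e_hf beyond "
                f"{self.additivity_tol} kcal/mol for rows: {list(bad)}",
                UserWarning, stacklevel=2)

    @classmethod
    def from_rows(cls, rows, **kw) -> "ComponentTable":
        """rows: iterable of (label, e_hl, e_el_10, e_ex_hl, e_del_hf, e_hf)
        tuples, dicts, or EDAResult-like objects."""
        recs = []
        for r in rows:
            if hasattr(r, "e_el_10") and hasattr(r, "label"):
                recs.append({"label": r.label, "e_hl": r.e_hl,
                             "e_el_10": r.e_el_10, "e_ex_hl": r.e_ex_hl,
                             "e_del_hf": r.e_del_hf, "e_hf": r.e_hf})
            elif isinstance(r, dict):
                recs.append({k: r[k] for k in ["label", *COMPONENTS]})
            else:
                lab, *vals = r
                recs.append(dict(zip(["label", *COMPONENTS], [lab, *vals])))
        return cls(pd.DataFrame.from_records(recs), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "ComponentTable":
        df = pd.read_csv(path)
        df = df.rename(columns=_CSV_COLUMNS)
        return cls(df, **kw)

    def to_csv(self, path) -> None:
        out = self.frame[["label", *COMPONENTS]].rename(
            columns={v: k for k, v in _CSV_COLUMNS.items()})
        out.to_csv(path, index=False)

    @property
    def labels(self) -> list[str]:
        return list(self.frame["label"])

    def select(self, include=None, exclude=()) -> "ComponentTable":
        df = self.frame
        if include is not None:
            df = df[df["label"].isin(list(include))]
        if exclude:
            df = df[~df["label"].isin(list(exclude))]
        return ComponentTable(df.reset_index(drop=True),
                              additivity_tol=self.additivity_tol)

    def row(self, label: str) -> pd.Series:
        match = self.frame[self.frame["label"] == label]
        if match.empty:
            raise StatsInputError(f"no row labelled {label!r}")
        return match.iloc[0]

    def __len__(self) -> int:
        return len(self.frame)


def load_reference_components() -> ComponentTable:
    """The packaged per-residue component table (kcal/mol)."""
    ref = importlib.resources.files("pocket_eda") / "data" / "table2.csv"
    import io
    return ComponentTable.from_csv(io.StringIO(ref.read_text()))


AMINO_ACID_EXCLUDE = ("ADP", "NICO")   # ligand sub-fragment rows


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation by the plain d_i^2 formula (no tie
    correction; ties produce average ranks and a TieWarning)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsInputError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise StatsInputError("need at least two observations")
    if len(np.unique(x)) < n or len(np.unique(y)) < n:
        warnings.warn("ties present; the plain formula has no tie "
                      "correction", TieWarning, stacklevel=2)
    d = rankdata(x) - rankdata(y)
    return float(1.0 - 6.0 * np.sum(d * d) / (n * (n * n - 1.0)))


@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho among the five components."""

    matrix: pd.DataFrame
    n: int

    def rho(self, a: str, b: str) -> float:
        return float(self.matrix.loc[a, b])

    def to_csv(self, path) -> None:
        self.matrix.round(4).to_csv(path, index_label="component")


def correlation_table(table: ComponentTable, include=None,
                      exclude=()) -> CorrelationMatrix:
    sub = table.select(include, exclude)
    if len(sub) < 2:
        raise StatsInputError("need at least 2 rows for correlations")
    mat = pd.DataFrame(np.eye(len(COMPONENTS)), index=COMPONENTS,
                       columns=COMPONENTS)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", TieWarning)
        for i, a in enumerate(COMPONENTS):
            for b in COMPONENTS[i + 1:]:
                r = spearman_rho(sub.frame[a].to_numpy(),
                                 sub.frame[b].to_numpy())
                mat.loc[a, b] = mat.loc[b, a] = r
    return CorrelationMatrix(mat, n=len(sub))


def covalency_ratio(row) -> float:
    """dE_del(HF) / eps_el(10) for one table row (mapping or Series)."""
    e_del, e_el = float(row["e_del_hf"]), float(row["e_el_10"])
    if e_el == 0.0:
        raise StatsInputError("electrostatic component is zero; "
                              "covalency ratio undefined")
    return e_del / e_el


def classify(ratio: float,
             threshold: float = COVALENCY_THRESHOLD) -> str:
    """Partially covalent iff ratio is strictly above the threshold."""
    return PARTIALLY_COVALENT if ratio > threshold else ELECTROSTATIC


@dataclass
class CovalencyReport:
    frame: pd.DataFrame    # label, hbond_distance, e_hf, ratio, classification

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["ratio"] = out["ratio"].round(2)
        out["e_hf"] = out["e_hf"].round(2)
        out.to_csv(path, index=False)


def covalency_report(table: ComponentTable, labels=None,
                     distances: dict[str, float] | None = None,
                     threshold: float = COVALENCY_THRESHOLD) -> CovalencyReport:
    """Covalency ratio + classification per selected row."""
    distances = (dict(REFERENCE_HBOND_DISTANCES) if distances is None
                 else distances)
    labels = list(labels) if labels is not None else list(distances)
    recs = []
    for lab in labels:
        row = table.row(lab)
        ratio = covalency_ratio(row)
        recs.append({"label": lab,
                     "hbond_distance": distances.get(lab, np.nan),
                     "e_hf": float(row["e_hf"]),
                     "ratio": ratio,
                     "classification": classify(ratio, threshold)})
    return CovalencyReport(pd.DataFrame.from_records(recs))
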