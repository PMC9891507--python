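"""Variable codebook and harmonization rules.

Population cohorts deliver survey answers as raw labels ("no", "occasionally",
"yes") with per-variable sentinel codes for refusals.  All downstream analysis
needs numeric, consistently oriented columns: for every phenotype a higher
value must mean *more* of that phenotype.  The codebook declares, per variable,
its role in the analysis (binary target, risk trait, confound, or social
indicator), its risk category, a monotone raw-label -> ordinal mapping, the
codes to treat as missing, and — for targets — the set of answers defining the
positive class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROLES = ("target", "risk_trait", "confound", "social_indicator")
CATEGORIES = ("lifestyle", "physical", "mental", "societal", "none")

__all__ = [
    "CodebookEntry",
    "Codebook",
    "CohortTable",
    "recode_variable",
    "binarize_target",
    "zscore",
]


@dataclass(frozen=True)
class CodebookEntry:
    """Metadata for one variable.

    ``mapping`` is an ordered label -> ordinal-code dict; the declared order is
    the "more of the phenotype" direction, so codes must be strictly
    increasing.  ``positive_labels`` (targets only) lists the raw answers that
    binarize to 1.
    """

    name: str
    role: str
    category: str = "none"
    mapping: dict[str, float] | None = None
    missing_codes: tuple[str, ...] = ()
    positive_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: unknown role {self.role!r}; expected one of {ROLES}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"{self.name}: unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        if self.mapping is not None:
            codes = list(self.mapping.values())
            if len(set(self.mapping)) != len(self.mapping):
                raise ValueError(f"{self.name}: duplicate raw labels in mapping")
            if any(b <= a for a, b in zip(codes, codes[1:])):
                raise ValueError(
                    f"{self.name}: mapping codes must be strictly increasing in the declared order"
                )
        if self.role == "target" and not self.positive_labels:
            raise ValueError(f"{self.name}: target variable requires a binarize rule")
        if self.role != "target" and self.positive_labels:
            raise ValueError(f"{self.name}: binarize rule only allowed for targets")


def recode_variable(raw_values: Sequence, entry: CodebookEntry) -> np.ndarray:
    """Map raw labels/codes to ordinal numerics; missing codes become NaN.

    With ``entry.mapping is None`` the input is passed through numerically
    (identity recode).  Any non-missing value absent from the mapping raises,
    listing the offending labels.
    """
    raw = pd.Series(raw_values)
    if entry.mapping is None:
        out = pd.to_numeric(raw.where(~raw.astype(str).isin(entry.missing_codes)), errors="raise")
        return out.to_numpy(dtype=float)
    labels = raw.astype(str).str.strip()
    is_missing = labels.isin(entry.missing_codes) | raw.isna()
    mapped = labels.map(entry.mapping)
    bad = sorted(set(labels[mapped.isna() & ~is_missing]))
    if bad:
        raise ValueError(f"{entry.name}: unmapped raw values {bad}")
    out = mapped.astype(float).to_numpy()
    out[is_missing.to_numpy()] = np.nan
    return out


def binarize_target(raw_values: Sequence, entry: CodebookEntry) -> np.ndarray:
    """Collapse a target variable's raw answers to {0, 1} (NaN for missing).

    Answers in ``entry.positive_labels`` become 1; any other answer listed in
    the mapping becomes 0; unknown answers raise.
    """
    if entry.role != "target":
        raise ValueError(f"{entry.name}: binarize_target requires a target-role entry")
    raw = pd.Series(raw_values)
    labels = raw.astype(str).str.strip()
    is_missing = labels.isin(entry.missing_codes) | raw.isna()
    known = set(entry.positive_labels) | set(entry.mapping or ())
    bad = sorted(set(labels[~is_missing]) - known)
    if bad:
        raise ValueError(f"{entry.name}: answers not covered by the binarize rule: {bad}")
    out = labels.isin(entry.positive_labels).astype(float).to_numpy()
    out[is_missing.to_numpy()] = np.nan
    return out


def zscore(column: Sequence[float]) -> np.ndarray:
    """Standardize a fully observed column to mean 0 and sample SD 1 (ddof=1)."""
    x = np.asarray(column, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore requires a 1-D column of length >= 2")
    if np.isnan(x).any():
        raise ValueError("zscore: column contains missing values; impute first")
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zscore: column has zero variance (constant column)")
    return (x - x.mean()) / sd


@dataclass
class Codebook:
    """Ordered collection of :class:`CodebookEntry`, loadable from CSV or JSON.

    CSV columns: ``variable, role, category, mapping, missing_codes,
    binarize_rule`` with ``mapping`` as ``label=code;label=code`` and the two
    list fields pipe-separated.
    """

    entries: dict[str, CodebookEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> CodebookEntry:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def names(self, role: str | None = None) -> list[str]:
        return [e.name for e in self if role is None or e.role == role]

    def category_of(self, name: str) -> str:
        return self.entries[name].category

    @classmethod
    def from_entries(cls, entries: Iterable[CodebookEntry]) -> "Codebook":
        return cls({e.name: e for e in entries})

    @classmethod
    def from_csv(cls, path: str | Path) -> "Codebook":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        entries = []
        for _, row in df.iterrows():
            mapping = None
            if row.get("mapping", ""):
                mapping = {}
                for pair in row["mapping"].split(";"):
                    label, code = pair.rsplit("=", 1)
                    mapping[label.strip()] = float(code)
            entries.append(
                CodebookEntry(
                    name=row["variable"],
                    role=row["role"],
                    category=row.get("category", "none") or "none",
                    mapping=mapping,
                    missing_codes=tuple(
                        s.strip() for s in row.get("missing_codes", "").split("|") if s.strip()
                    ),
                    positive_labels=tuple(
                        s.strip() for s in row.get("binarize_rule", "").split("|") if s.strip()
                    ),
                )
            )
        return cls.from_entries(entries)

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        with open(path) as fh:
            raw = json.load(fh)
        entries = [
            CodebookEntry(
                name=d["variable"],
                role=d["role"],
                category=d.get("category", "none"),
                mapping=dict(d["mapping"]) if d.get("mapping") else None,
                missing_codes=tuple(d.get("missing_codes", ())),
                positive_labels=tuple(d.get("binarize_rule", ())),
            )
            for d in raw
        ]
        return cls.from_entries(entries)


class CohortTable:
    """Participant-by-variable numeric table with declared column roles.

    ``data`` holds one row per participant with a ``participant_id`` column;
    every other column carries a role (target / risk_trait / confound /
    social_indicator) and, optionally, a risk category.  Missing values are
    NaN and serialize to empty CSV fields.
    """

    ID = "participant_id"

    def __init__(
        self,
        data: pd.DataFrame,
        roles: Mapping[str, str],
        categories: Mapping[str, str] | None = None,
    ) -> None:
        if self.ID not in data.columns:
            raise ValueError(f"table must contain a {self.ID!r} column")
        if data[self.ID].duplicated().any():
            raise ValueError("participant_id values must be unique")
        value_cols = [c for c in data.columns if c != self.ID]
        missing_roles = [c for c in value_cols if c not in roles]
        if missing_roles:
            raise ValueError(f"columns without a declared role: {missing_roles}")
        for col, role in roles.items():
            if role not in ROLES:
                raise ValueError(f"{col}: unknown role {role!r}")
        for col in [c for c in value_cols if roles[c] == "target"]:
            vals = data[col].dropna().unique()
            if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
                raise ValueError(f"target column {col!r} must contain only 0/1/missing")
        self.data = data.reset_index(drop=True)
        self.roles = {c: roles[c] for c in value_cols}
        self.categories = dict(categories or {})

    # -- role views ---------------------------------------------------------
    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    @property
    def targets(self) -> list[str]:
        return self.columns_with_role("target")

    @property
    def risk_traits(self) -> list[str]:
        return self.columns_with_role("risk_trait")

    @property
    def confounds(self) -> list[str]:
        return self.columns_with_role("confound")

    @property
    def social_indicators(self) -> list[str]:
        return self.columns_with_role("social_indicator")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def p(self) -> int:
        return len(self.risk_traits)

    @property
    def q(self) -> int:
        return len(self.social_indicators)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.roles), dict(self.categories))

    def zscored(self, columns: Iterable[str] | None = None) -> "CohortTable":
        """Return a copy with the given columns (default: risk traits) z-scored."""
        out = self.copy()
        for col in list(columns) if columns is not None else self.risk_traits:
            out.data[col] = zscore(self.data[col].to_numpy(dtype=float))
        return out

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        roles: Mapping[str, str] | None = None,
        codebook: Codebook | None = None,
        categories: Mapping[str, str] | None = None,
    ) -> "CohortTable":
        if roles is None:
            if codebook is None:
                raise ValueError("provide either a role map or a codebook")
            roles = {e.name: e.role for e in codebook}
            categories = {e.name: e.category for e in codebook}
        df = pd.read_csv(path)
        roles = {c: roles[c] for c in df.columns if c != cls.ID}
        return cls(df, roles, categories)

    def missing_fraction(self, columns: Iterable[str] | None = None) -> float:
        cols = list(columns) if columns is not None else self.risk_traits
        if not cols:
            return 0.0
        return float(self.data[cols].isna().to_numpy().mean())
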