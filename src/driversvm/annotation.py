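"""Gene role annotation: canonical drivers, candidates, false positives.

Canonical drivers (experimentally validated cancer genes) carry an optional
mode-of-action role — oncogene (OG), tumour suppressor (TSG) or both — that
controls the gain/loss-of-function training filter.  Candidate cancer genes
come from sequencing screens; false positives are recurrently mis-called
genes used only for assessment.  Category precedence is
canonical > candidate > false_positive > rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError

ROLES = frozenset({"OG", "TSG", "both"})
CATEGORIES = ("canonical", "candidate", "false_positive", "rest")


@dataclass
class GeneAnnotation:
    """Role lists with category precedence canonical > candidate > false_positive > rest."""

    canonical_roles: dict[str, str | None] = field(default_factory=dict)
    candidates: set[str] = field(default_factory=set)
    false_positives: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, role in self.canonical_roles.items():
            if role is not None and role not in ROLES:
                raise InputError(f"unknown role {role!r} for canonical driver {gene}")
        # precedence resolves overlaps between the input lists
        self.candidates = set(self.candidates) - set(self.canonical_roles)
        self.false_positives = set(self.false_positives) - set(self.canonical_roles) - self.candidates

    @property
    def canonical(self) -> set[str]:
        return set(self.canonical_roles)

    def role(self, gene: str) -> str | None:
        return self.canonical_roles.get(gene)

    def category(self, gene: str) -> str:
        if gene in self.canonical_roles:
            return "canonical"
        if gene in self.candidates:
            return "candidate"
        if gene in self.false_positives:
            return "false_positive"
        return "rest"

    def categories(self, genes) -> pd.Series:
        """Vectorised :meth:`category` over an iterable of gene symbols."""
        return pd.Series([self.category(g) for g in genes], index=None)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneAnnotation":
        """Build from a table with columns ``gene``, ``category`` and optional ``role``."""
        required = {"gene", "category"}
        if not required <= set(df.columns):
            raise InputError(f"annotation table needs columns {sorted(required)}")
        bad = set(df["category"].unique()) - {"canonical", "candidate", "false_positive"}
        if bad:
            raise InputError(f"unknown annotation categories: {sorted(bad)}")
        canonical: dict[str, str | None] = {}
        candidates: set[str] = set()
        fps: set[str] = set()
        for row in df.itertuples(index=False):
            gene = str(row.gene).upper()
            if row.category == "canonical":
                role = getattr(row, "role", None)
                if role is not None and (pd.isna(role) or role == ""):
                    role = None
                if gene in canonical and canonical[gene] != role:
                    raise InputError(f"conflicting roles for canonical driver {gene}")
                canonical[gene] = role
            elif row.category == "candidate":
                candidates.add(gene)
            else:
                fps.add(gene)
        return cls(canonical, candidates, fps)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "category": "canonical", "role": r if r is not None else ""}
            for g, r in sorted(self.canonical_roles.items())
        ]
        rows += [{"gene": g, "category": "candidate", "role": ""} for g in sorted(self.candidates)]
        rows += [{"gene": g, "category": "false_positive", "role": ""} for g in sorted(self.false_positives)]
        return pd.DataFrame(rows, columns=["gene", "category", "role"])
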