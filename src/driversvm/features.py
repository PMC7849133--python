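"""Per-(sample, gene) feature engineering for driver prioritisation.

Builds the 26-dimensional feature vectors — 7 molecular features describing a
gene's somatic alterations in one sample, and 19 systems-level properties of
the gene itself — that the one-class SVMs consume.  Only "damaged" genes are
kept: a gene carrying at least one truncating, non-truncating damaging or
hotspot mutation, an amplification, or a deletion in that sample.

Also provides a correlation audit (`select_features`) that flags highly
inter-correlated features for removal, since correlated inputs hinder SVM
performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

#: Controlled vocabulary for mutation consequence classes.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "stop_gained",
        "stop_lost",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "synonymous",
        "other",
    }
)

_TRUNCATING_CLASSES = frozenset({"stop_gained", "stop_lost", "frameshift", "splice_site"})
_NONTRUNCATING_CLASSES = frozenset({"missense", "inframe_indel"})

#: The 7 molecular features (somatic alteration status of the gene in the sample).
MOLECULAR_FEATURES = [
    "mutational_load",
    "n_nontrunc_damaging",
    "n_truncating",
    "n_hotspot",
    "copy_number",
    "is_amplified",
    "is_deleted",
]

#: The 19 systems-level properties (global gene attributes).
SYSTEMS_FEATURES = [
    "is_duplicated",
    "is_ohnolog",
    "pct_essential_lines",
    "is_essential",
    "n_tissues_gene_expr",
    "expr_0_tissues",
    "expr_7_36_tissues",
    "n_tissues_protein_expr",
    "protein_expr_ge41",
    "ppin_degree",
    "is_hub",
    "ppin_betweenness",
    "ppin_clustering",
    "n_complexes",
    "n_mirnas",
    "origin_premetazoan",
    "origin_metazoan",
    "origin_vertebrate",
    "origin_postvertebrate",
]

#: All 26 model features, in canonical column order.
ALL_FEATURES = MOLECULAR_FEATURES + SYSTEMS_FEATURES

#: Property columns dropped if present: long, multi-domain proteins are a
#: hallmark of recurrence-method false positives, and these two features
#: degrade the separation of drivers from false positives.
EXCLUDED_PROPERTIES = ["protein_length", "n_domains"]

# Default copy-number thresholds.  Amplification: copy number at least twice
# the sample ploidy; deletion: copy number below one.  Overridable.
AMPLIFICATION_PLOIDY_MULTIPLE = 2.0
DELETION_COPY_NUMBER = 1.0


def classify_mutation(variant_class: str, damaging_flag: bool = False, hotspot_flag: bool = False) -> str:
    """Assign a single mutation record to a damaging category.

    Categories: ``truncating`` (stop gain/loss, frameshift, splice site),
    ``nontruncating_damaging`` (missense or in-frame indel flagged damaging by
    the upstream function-impact consensus), ``hotspot_only`` (a record whose
    only damaging evidence is its hotspot flag), ``nontruncating_other``
    (missense/in-frame without damaging evidence) and ``not_damaging``
    (synonymous and other classes).  The hotspot flag itself is orthogonal:
    a damaging missense at a hotspot still counts as a hotspot mutation.

    Raises
    ------
    InputError
        If `variant_class` is outside the controlled vocabulary.
    """
    if variant_class not in VARIANT_CLASSES:
        raise InputError(f"unknown variant_class: {variant_class!r}")
    if variant_class in _TRUNCATING_CLASSES:
        return "truncating"
    if variant_class in _NONTRUNCATING_CLASSES and damaging_flag:
        return "nontruncating_damaging"
    if hotspot_flag:
        return "hotspot_only"
    if variant_class in _NONTRUNCATING_CLASSES:
        return "nontruncating_other"
    return "not_damaging"


def _mutation_categories(mutations: pd.DataFrame) -> pd.DataFrame:
    """Vectorised mutation classification; adds category/count helper columns."""
    bad = set(mutations["variant_class"].unique()) - VARIANT_CLASSES
    if bad:
        raise InputError(f"unknown variant_class: {sorted(bad)!r}")
    df = mutations.copy()
    vc = df["variant_class"]
    damaging = df["damaging_flag"].astype(bool)
    df["is_truncating"] = vc.isin(_TRUNCATING_CLASSES)
    df["is_nontrunc_damaging"] = vc.isin(_NONTRUNCATING_CLASSES) & damaging
    df["is_hotspot"] = df["hotspot_flag"].astype(bool)
    df["is_nonsynonymous"] = vc != "synonymous"
    return df


def build_molecular_features(
    mutations: pd.DataFrame,
    cnvs: pd.DataFrame | None = None,
    ploidy: pd.DataFrame | None = None,
    *,
    amplification_multiple: float = AMPLIFICATION_PLOIDY_MULTIPLE,
    deletion_threshold: float = DELETION_COPY_NUMBER,
) -> pd.DataFrame:
    """Aggregate mutation and copy-number tables into molecular features.

    Parameters
    ----------
    mutations
        Columns ``sample``, ``gene``, ``variant_class``, ``damaging_flag``,
        ``hotspot_flag``; one row per somatic variant.
    cnvs
        Columns ``sample``, ``gene``, ``copy_number``; gene-level absolute
        copy number.  Optional.
    ploidy
        Columns ``sample``, ``ploidy``; required whenever `cnvs` is given.

    Returns
    -------
    DataFrame with columns ``sample``, ``gene`` and the 7 molecular features,
    one row per damaged (sample, gene) pair.  ``mutational_load`` counts
    non-synonymous variants; ``copy_number`` defaults to the sample ploidy
    (neutral) for genes without a copy-number call.
    """
    frames = []
    ploidy_map: dict[str, float] = {}
    if ploidy is not None:
        if ploidy["sample"].duplicated().any():
            dups = ploidy.loc[ploidy["sample"].duplicated(), "sample"].tolist()
            raise InputError(f"duplicated samples in ploidy table: {dups}")
        ploidy_map = dict(zip(ploidy["sample"], ploidy["ploidy"].astype(float)))

    if len(mutations):
        df = _mutation_categories(mutations)
        agg = (
            df.groupby(["sample", "gene"], sort=True)
            .agg(
                mutational_load=("is_nonsynonymous", "sum"),
                n_nontrunc_damaging=("is_nontrunc_damaging", "sum"),
                n_truncating=("is_truncating", "sum"),
                n_hotspot=("is_hotspot", "sum"),
            )
            .reset_index()
        )
        frames.append(agg)

    if cnvs is not None and len(cnvs):
        missing = sorted(set(cnvs["sample"]) - set(ploidy_map))
        if missing:
            raise InputError(f"copy-number records without a ploidy value for samples: {missing}")
        cn = cnvs[["sample", "gene", "copy_number"]].copy()
        cn["copy_number"] = cn["copy_number"].astype(float)
        if (cn["copy_number"] < 0).any():
            raise InputError("negative copy_number values")
        cn["_ploidy"] = cn["sample"].map(ploidy_map)
        cn["is_amplified"] = cn["copy_number"] >= amplification_multiple * cn["_ploidy"]
        cn["is_deleted"] = cn["copy_number"] < deletion_threshold
        frames.append(cn.drop(columns="_ploidy"))

    if not frames:
        raise InputError("no mutation or copy-number records supplied")

    merged = frames[0]
    for extra in frames[1:]:
        merged = merged.merge(extra, on=["sample", "gene"], how="outer")
    for col in ("mutational_load", "n_nontrunc_damaging", "n_truncating", "n_hotspot"):
        if col not in merged:
            merged[col] = 0
        merged[col] = merged[col].fillna(0).astype(int)
    for col in ("is_amplified", "is_deleted"):
        if col not in merged:
            merged[col] = False
        merged[col] = merged[col].astype("boolean").fillna(False).astype(bool)
    if "copy_number" not in merged:
        merged["copy_number"] = np.nan
    # genes without a CNV call sit at the sample's ploidy (copy-neutral)
    neutral = merged["sample"].map(ploidy_map).fillna(2.0)
    merged["copy_number"] = merged["copy_number"].astype(float).fillna(neutral)

    damaged = (
        (merged["n_truncating"] > 0)
        | (merged["n_nontrunc_damaging"] > 0)
        | (merged["n_hotspot"] > 0)
        | merged["is_amplified"]
        | merged["is_deleted"]
    )
    out = merged.loc[damaged, ["sample", "gene"] + MOLECULAR_FEATURES]
    return out.sort_values(["sample", "gene"], kind="mergesort").reset_index(drop=True)


@dataclass
class JoinReport:
    """Accounting for the molecular/systems-level join."""

    n_input: int
    n_output: int
    dropped_genes: list[str]

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_output


def join_features(molecular: pd.DataFrame, properties: pd.DataFrame) -> tuple[pd.DataFrame, JoinReport]:
    """Inner-join molecular features with the systems-level property table.

    Genes absent from the property table are dropped and reported.  The
    columns in :data:`EXCLUDED_PROPERTIES` are discarded with a logged notice
    if present.  Raises :class:`InputError` on a duplicated gene key or an
    empty join result.
    """
    if properties["gene"].duplicated().any():
        dups = sorted(properties.loc[properties["gene"].duplicated(), "gene"].unique())
        raise InputError(f"duplicated gene keys in property table: {dups}")
    props = properties
    present_excluded = [c for c in EXCLUDED_PROPERTIES if c in props.columns]
    if present_excluded:
        logger.info("ignoring excluded property columns: %s", present_excluded)
        props = props.drop(columns=present_excluded)
    missing_cols = [c for c in SYSTEMS_FEATURES if c not in props.columns]
    if missing_cols:
        raise InputError(f"property table missing columns: {missing_cols}")
    props = props[["gene"] + SYSTEMS_FEATURES]

    joined = molecular.merge(props, on="gene", how="inner")
    joined = joined.sort_values(["sample", "gene"], kind="mergesort").reset_index(drop=True)
    dropped = sorted(set(molecular["gene"]) - set(props["gene"]))
    report = JoinReport(n_input=len(molecular), n_output=len(joined), dropped_genes=dropped)
    if joined.empty:
        raise InputError("no annotatable damaged genes: join of molecular features and properties is empty")
    if report.n_dropped:
        logger.info("dropped %d damaged entries in %d genes lacking properties", report.n_dropped, len(dropped))
    return joined, report


def select_features(
    table: pd.DataFrame,
    r_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Flag inter-correlated features for removal.

    All pairwise Pearson correlations between feature columns are tested;
    p-values are Benjamini–Hochberg adjusted.  Pairs with ``|r| >
    r_threshold`` and ``FDR < fdr_threshold`` are deemed redundant, and
    features are greedily removed: at each step the feature participating in
    the most remaining significant pairs is dropped (ties broken by column
    order) until no significant pair survives.

    Returns the retained feature names (original order) and a report of all
    tested pairs with ``r``, ``pvalue``, ``fdr`` and ``significant`` columns.
    This is an audit tool: the default pipeline uses the pre-vetted 26-feature
    set and does not re-run selection per cohort.
    """
    cols = [c for c in table.columns if c not in ("sample", "gene")]
    if len(table) < 3:
        raise InputError("need at least 3 rows for correlation-based selection")
    mat = {}
    for c in cols:
        vals = table[c]
        if vals.dtype == bool:
            vals = vals.astype(int)
        if not np.issubdtype(np.asarray(vals).dtype, np.number):
            raise InputError(f"non-numeric feature column: {c!r}")
        mat[c] = np.asarray(vals, dtype=float)

    records = []
    for a, b in combinations(cols, 2):
        x, y = mat[a], mat[b]
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, 1.0
        else:
            r, p = stats.pearsonr(x, y)
        records.append((a, b, r, p))
    report = pd.DataFrame(records, columns=["feature_a", "feature_b", "r", "pvalue"])
    report["fdr"] = multipletests(report["pvalue"].values, method="fdr_bh")[1]
    report["significant"] = (report["r"].abs() > r_threshold) & (report["fdr"] < fdr_threshold)

    sig_pairs = {
        frozenset((a, b))
        for a, b in zip(report.loc[report["significant"], "feature_a"], report.loc[report["significant"], "feature_b"])
    }
    removed: list[str] = []
    while sig_pairs:
        counts = {c: sum(c in pair for pair in sig_pairs) for c in cols}
        worst = max(cols, key=lambda c: (counts[c], -cols.index(c)))
        removed.append(worst)
        sig_pairs = {pair for pair in sig_pairs if worst not in pair}
    retained = [c for c in cols if c not in removed]
    return retained, report
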