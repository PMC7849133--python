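"""Cohort simulation and fully synthetic fixture generation.

Two generators live here:

``simulate_cohort``
    Builds simulated cancer cohorts by burden- and ploidy-matched resampling
    from a donor cohort.  Each simulated sample is assigned a target damaging
    mutation burden and a target ploidy drawn from the empirical donor
    distributions; its mutation-damaged genes are then drawn (without
    replacement, payloads copied verbatim) from donor samples whose burden
    lies within ±10% of the target, and its CNV-damaged genes from donors
    whose ploidy lies within ±0.1 of the target.  This preserves the marginal
    burden/ploidy distributions and per-gene alteration frequencies of the
    donor cohort while shuffling gene co-occurrence across samples.

``generate_fixture_cohort``
    Fabricates a donor-style cohort from scratch with a planted set of driver
    genes whose systems-level properties are shifted towards the profile of
    real cancer genes (higher network degree and betweenness, essentiality,
    broader expression, more complexes and targeting miRNAs, earlier
    evolutionary origin, lower duplicability) and whose damaging-alteration
    rate is elevated.  It emits every input table the pipeline needs plus the
    ground-truth driver labels, so the whole method is testable end to end
    without any external data.

Burden is counted as the number of genes damaged by mutation in a sample
(each damaged gene contributes one payload of one or more variant records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneAnnotation
from .errors import InputError
from .features import SYSTEMS_FEATURES, _mutation_categories

MAX_RETRIES = 10


@dataclass
class SimulationSpec:
    """Resampling windows for the cohort simulator.

    ``mut_tolerance`` is relative (±10% of the target burden); the ploidy
    tolerance is absolute (±0.1).
    """

    n_samples: int
    mut_tolerance: float = 0.10
    ploidy_tolerance: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise InputError("n_samples must be positive")
        if self.mut_tolerance <= 0 or self.ploidy_tolerance <= 0:
            raise InputError("tolerances must be positive")


@dataclass
class DonorSample:
    """One donor sample: ploidy plus its damaged-gene payloads.

    ``mut_genes`` maps gene -> list of mutation record dicts (the gene's
    variants in this sample); ``cnv_genes`` maps gene -> copy-number value.
    """

    sample_id: str
    ploidy: float
    mut_genes: dict[str, list[dict]] = field(default_factory=dict)
    cnv_genes: dict[str, float] = field(default_factory=dict)

    @property
    def burden(self) -> int:
        return len(self.mut_genes)


def donors_from_tables(
    mutations: pd.DataFrame,
    cnvs: pd.DataFrame,
    ploidy: pd.DataFrame,
    *,
    amplification_multiple: float = 2.0,
    deletion_threshold: float = 1.0,
) -> list[DonorSample]:
    """Assemble :class:`DonorSample` objects from the standard input tables.

    A gene enters ``mut_genes`` if it carries at least one damaging mutation
    (truncating, non-truncating damaging, or hotspot) in the sample, with all
    of the gene's records as payload; it enters ``cnv_genes`` if amplified or
    deleted relative to the sample's ploidy.
    """
    ploidy_map = dict(zip(ploidy["sample"].astype(str), ploidy["ploidy"].astype(float)))
    donors: dict[str, DonorSample] = {
        s: DonorSample(sample_id=s, ploidy=p) for s, p in sorted(ploidy_map.items())
    }
    if len(mutations):
        df = _mutation_categories(mutations)
        df["_damaging"] = df["is_truncating"] | df["is_nontrunc_damaging"] | df["is_hotspot"]
        keep = df.groupby(["sample", "gene"])["_damaging"].transform("any")
        for (sample, gene), grp in df[keep].groupby(["sample", "gene"], sort=True):
            if sample not in donors:
                raise InputError(f"mutation records for sample {sample!r} without a ploidy value")
            payload = grp[["variant_class", "damaging_flag", "hotspot_flag"]].to_dict("records")
            donors[sample].mut_genes[gene] = payload
    if cnvs is not None and len(cnvs):
        for row in cnvs.itertuples(index=False):
            sample = str(row.sample)
            if sample not in donors:
                raise InputError(f"copy-number records for sample {sample!r} without a ploidy value")
            pl = donors[sample].ploidy
            cn = float(row.copy_number)
            if cn >= amplification_multiple * pl or cn < deletion_threshold:
                donors[sample].cnv_genes[row.gene] = cn
    return [d for _, d in sorted(donors.items())]


def _sorted_pool(items: dict[str, list]) -> list[str]:
    return sorted(items)


def simulate_cohort(
    donors: list[DonorSample], spec: SimulationSpec, with_targets: bool = False
):
    """Simulate a cohort by burden/ploidy-matched resampling from `donors`.

    Returns ``(mutations, cnvs, ploidy)`` tables in the standard input
    schemas (plus a per-sample table of the drawn target burden/ploidy when
    `with_targets` is set).  Every simulated sample's mutation burden equals
    its drawn target exactly, its ploidy equals the drawn target, and every
    alteration payload is copied verbatim from a donor inside the matching
    window.
    """
    if not donors:
        raise InputError("empty donor cohort")
    rng = np.random.default_rng(spec.seed)
    burdens = np.array([d.burden for d in donors])
    ploidies = np.array([d.ploidy for d in donors])
    cnv_counts = np.array([len(d.cnv_genes) for d in donors])

    mut_rows: list[dict] = []
    cnv_rows: list[dict] = []
    ploidy_rows: list[dict] = []
    target_rows: list[dict] = []

    for i in range(spec.n_samples):
        sid = f"SIM_{i + 1:05d}"

        # --- mutation-damaged genes, matched on damaging mutation burden ---
        # The pool is the multiset of (gene, payload) occurrences across
        # eligible donors, so genes damaged in many donors are drawn
        # proportionally more often, preserving per-gene frequencies.
        target = None
        occurrences: list[tuple[str, list[dict]]] = []
        for _ in range(MAX_RETRIES):
            cand = int(rng.choice(burdens))
            lo, hi = cand * (1 - spec.mut_tolerance), cand * (1 + spec.mut_tolerance)
            occurrences = [
                (gene, payload)
                for d in donors
                if lo <= d.burden <= hi
                for gene, payload in sorted(d.mut_genes.items())
            ]
            if len({g for g, _ in occurrences}) >= cand:
                target = cand
                break
        if target is None:
            raise InputError(f"no donor pool large enough for target burden {cand}")
        picked: dict[str, list[dict]] = {}
        for idx in rng.permutation(len(occurrences)):
            gene, payload = occurrences[idx]
            if gene not in picked:
                picked[gene] = payload
                if len(picked) == target:
                    break
        for gene in sorted(picked):
            for rec in picked[gene]:
                mut_rows.append({"sample": sid, "gene": gene, **rec})

        # --- CNV-damaged genes, matched on ploidy ---
        target_ploidy = None
        cnv_occurrences: list[tuple[str, float]] = []
        n_cnv = 0
        for _ in range(MAX_RETRIES):
            cand_p = float(rng.choice(ploidies))
            eligible = [
                d for d in donors if abs(d.ploidy - cand_p) <= spec.ploidy_tolerance
            ]
            counts = [len(d.cnv_genes) for d in eligible]
            if not counts:
                continue
            n_cnv_cand = int(rng.choice(counts))
            cnv_occurrences = [
                (gene, cn) for d in eligible for gene, cn in sorted(d.cnv_genes.items())
            ]
            if len({g for g, _ in cnv_occurrences}) >= n_cnv_cand:
                target_ploidy = cand_p
                n_cnv = n_cnv_cand
                break
        if target_ploidy is None:
            raise InputError(f"no donor pool for target ploidy {cand_p}")
        if n_cnv:
            picked_cnv: dict[str, float] = {}
            for idx in rng.permutation(len(cnv_occurrences)):
                gene, cn = cnv_occurrences[idx]
                if gene not in picked_cnv:
                    picked_cnv[gene] = cn
                    if len(picked_cnv) == n_cnv:
                        break
            for gene in sorted(picked_cnv):
                cnv_rows.append({"sample": sid, "gene": gene, "copy_number": picked_cnv[gene]})
        ploidy_rows.append({"sample": sid, "ploidy": target_ploidy})
        target_rows.append({"sample": sid, "target_burden": target, "target_ploidy": target_ploidy})

    mut_cols = ["sample", "gene", "variant_class", "damaging_flag", "hotspot_flag"]
    mutations = pd.DataFrame(mut_rows, columns=mut_cols)
    cnvs = pd.DataFrame(cnv_rows, columns=["sample", "gene", "copy_number"])
    ploidy = pd.DataFrame(ploidy_rows, columns=["sample", "ploidy"])
    if with_targets:
        targets = pd.DataFrame(target_rows, columns=["sample", "target_burden", "target_ploidy"])
        return mutations, cnvs, ploidy, targets
    return mutations, cnvs, ploidy


def alteration_frequencies(mutations: pd.DataFrame, cnvs: pd.DataFrame, n_samples: int) -> pd.Series:
    """Per-gene damaging-alteration frequency: fraction of samples where the
    gene is damaged by mutation or CNV (CNV tables here already contain only
    damaging calls)."""
    pairs = set()
    if len(mutations):
        df = _mutation_categories(mutations)
        dmg = df[df["is_truncating"] | df["is_nontrunc_damaging"] | df["is_hotspot"]]
        pairs |= set(zip(dmg["sample"], dmg["gene"]))
    if cnvs is not None and len(cnvs):
        pairs |= set(zip(cnvs["sample"], cnvs["gene"]))
    counts = pd.Series([g for _, g in pairs]).value_counts()
    return counts / n_samples


def cohort_fidelity_report(
    donor_tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
    simulated_tables: tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame],
) -> pd.DataFrame:
    """Compare donor and simulated cohorts: per-gene alteration-frequency
    correlation, burden and ploidy location shifts.

    Both arguments are ``(mutations, cnvs, ploidy)`` triples.  Returns a
    two-column ``metric``/``value`` table; the frequency correlation is NaN
    when the gene universes are disjoint.
    """
    d_mut, d_cnv, d_pl = donor_tables
    s_mut, s_cnv, s_pl = simulated_tables
    if (len(d_mut) == 0 and len(d_cnv) == 0) or (len(s_mut) == 0 and len(s_cnv) == 0):
        raise InputError("empty cohort in fidelity comparison")

    freq_d = alteration_frequencies(d_mut, d_cnv, d_pl["sample"].nunique())
    freq_s = alteration_frequencies(s_mut, s_cnv, s_pl["sample"].nunique())
    shared = freq_d.index.intersection(freq_s.index)
    union = freq_d.index.union(freq_s.index)
    aligned_d = freq_d.reindex(union, fill_value=0.0)
    aligned_s = freq_s.reindex(union, fill_value=0.0)
    if len(shared) == 0 or aligned_d.std() == 0 or aligned_s.std() == 0:
        freq_r = np.nan
    else:
        freq_r = float(stats.pearsonr(aligned_d, aligned_s)[0])

    def burdens(mut: pd.DataFrame, pl: pd.DataFrame) -> pd.Series:
        if not len(mut):
            return pd.Series(0, index=pl["sample"].unique())
        df = _mutation_categories(mut)
        dmg = df[df["is_truncating"] | df["is_nontrunc_damaging"] | df["is_hotspot"]]
        b = dmg.groupby("sample")["gene"].nunique()
        return b.reindex(pl["sample"].unique(), fill_value=0)

    bd, bs = burdens(d_mut, d_pl), burdens(s_mut, s_pl)
    rows = [
        ("n_donor_samples", float(d_pl["sample"].nunique())),
        ("n_simulated_samples", float(s_pl["sample"].nunique())),
        ("gene_frequency_pearson_r", freq_r),
        ("n_shared_genes", float(len(shared))),
        ("donor_median_burden", float(bd.median())),
        ("simulated_median_burden", float(bs.median())),
        ("donor_median_ploidy", float(d_pl["ploidy"].median())),
        ("simulated_median_ploidy", float(s_pl["ploidy"].median())),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])


# ---------------------------------------------------------------------------
# Fully synthetic fixture cohorts with planted drivers
# ---------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    """Generative parameters for a synthetic cohort with planted drivers.

    ``feature_shift`` scales the separation between driver and non-driver
    systems-level feature distributions (0 = identical, 1 = default profile
    mirroring the empirical trends of real cancer genes);
    ``driver_rate_multiplier`` multiplies the probability that a damaging
    alteration hits a planted driver.  ``mean_mut_genes`` is the average
    number of mutation-damaged genes per sample and ``mean_cnv_genes`` the
    average number of amplified/deleted genes.
    """

    n_genes: int = 2000
    n_driver_genes: int = 50
    n_samples: int = 100
    n_candidate_genes: int = 100
    n_false_positive_genes: int = 20
    feature_shift: float = 1.0
    driver_rate_multiplier: float = 8.0
    mean_mut_genes: float = 33.0
    mean_cnv_genes: float = 8.0
    hub_degree: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_driver_genes >= self.n_genes:
            raise InputError("n_driver_genes must be smaller than n_genes")
        if self.n_samples <= 0 or self.n_genes <= 0:
            raise InputError("n_samples and n_genes must be positive")


@dataclass
class FixtureCohort:
    """Everything the pipeline needs, plus ground truth."""

    mutations: pd.DataFrame
    cnvs: pd.DataFrame
    ploidy: pd.DataFrame
    properties: pd.DataFrame
    annotation: GeneAnnotation
    driver_genes: list[str]
    driver_roles: dict[str, str]


def _interp_probs(base: np.ndarray, target: np.ndarray, s: float) -> np.ndarray:
    p = base + min(s, 1.0) * (target - base)
    return p / p.sum()


def _gene_properties(genes: list[str], is_driver: np.ndarray, spec: FixtureSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Class-conditional systems-level properties.

    Non-drivers follow genome-wide baselines; drivers are shifted towards the
    systems-level profile of cancer genes by ``spec.feature_shift``.
    """
    n = len(genes)
    s = spec.feature_shift
    d = is_driver.astype(float) * s

    props = pd.DataFrame({"gene": genes})
    props["is_duplicated"] = rng.random(n) < np.clip(0.45 - 0.20 * d, 0, 1)
    props["is_ohnolog"] = rng.random(n) < np.clip(0.20 + 0.25 * d, 0, 1)
    pct = np.clip(rng.normal(5 + 15 * d, 5 + 5 * d), 0, 100)
    props["pct_essential_lines"] = pct
    props["is_essential"] = rng.random(n) < np.clip(0.05 + 0.25 * d, 0, 1)
    n_tis = rng.binomial(37, np.clip(0.45 + 0.25 * d, 0, 0.97))
    props["n_tissues_gene_expr"] = n_tis
    props["expr_0_tissues"] = n_tis == 0
    props["expr_7_36_tissues"] = (n_tis >= 7) & (n_tis <= 36)
    n_prot = rng.binomial(44, np.clip(0.40 + 0.25 * d, 0, 0.97))
    props["n_tissues_protein_expr"] = n_prot
    props["protein_expr_ge41"] = n_prot >= 41
    degree = np.floor(np.exp(rng.normal(2.0 + 0.9 * d, 1.0))).astype(int)
    props["ppin_degree"] = degree
    props["is_hub"] = degree >= spec.hub_degree
    props["ppin_betweenness"] = degree ** 1.3 * np.abs(rng.normal(1.0, 0.3, n))
    props["ppin_clustering"] = np.clip(rng.beta(2, 8 + 2 * np.maximum(d, 0) + 1e-9), 0, 1)
    props["n_complexes"] = rng.poisson(0.5 + 2.5 * d)
    props["n_mirnas"] = rng.poisson(3.0 + 8.0 * d)

    base_origin = np.array([0.25, 0.45, 0.25, 0.05])
    driver_origin = np.array([0.55, 0.35, 0.08, 0.02])
    origin_cols = ["origin_premetazoan", "origin_metazoan", "origin_vertebrate", "origin_postvertebrate"]
    origins = np.empty(n, dtype=int)
    for flag, probs in ((False, base_origin), (True, _interp_probs(base_origin, driver_origin, s))):
        mask = is_driver == flag
        origins[mask] = rng.choice(4, size=int(mask.sum()), p=probs)
    for j, col in enumerate(origin_cols):
        props[col] = origins == j
    return props[["gene"] + SYSTEMS_FEATURES]


_OG_CLASSES = ["missense", "missense", "inframe_indel"]
_TSG_CLASSES = ["stop_gained", "frameshift", "splice_site", "stop_lost"]
_PASSENGER_CLASSES = ["missense", "stop_gained", "frameshift", "inframe_indel", "splice_site"]


def _damaging_record(role: str | None, rng: np.random.Generator) -> dict:
    """One damaging mutation record, consistent with the gene's mode of action."""
    if role == "both":
        role = "OG" if rng.random() < 0.5 else "TSG"
    if role == "OG":
        vc = _OG_CLASSES[rng.integers(len(_OG_CLASSES))]
        return {"variant_class": vc, "damaging_flag": True, "hotspot_flag": bool(rng.random() < 0.30)}
    if role == "TSG":
        vc = _TSG_CLASSES[rng.integers(len(_TSG_CLASSES))]
        return {"variant_class": vc, "damaging_flag": False, "hotspot_flag": False}
    vc = _PASSENGER_CLASSES[rng.integers(len(_PASSENGER_CLASSES))]
    damaging = vc in ("missense", "inframe_indel")
    return {"variant_class": vc, "damaging_flag": damaging, "hotspot_flag": bool(rng.random() < 0.02)}


def generate_fixture_cohort(spec: FixtureSpec) -> FixtureCohort:
    """Fabricate a donor-style cohort with planted driver signal.

    Planted drivers get systems-level features shifted by ``feature_shift``
    and damaging alterations at ``driver_rate_multiplier`` times the
    background rate, with mode-of-action-consistent alteration types
    (oncogenes: damaging missense / hotspot / amplification; tumour
    suppressors: truncating mutations / deletion).  Roughly 30% of planted
    drivers carry no mode-of-action role: they are annotated canonical but
    excluded from training, mirroring how a sizeable minority of real
    canonical drivers cannot be classed as OG or TSG and serve for assessment
    instead.  Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(spec.n_genes)]

    driver_idx = rng.choice(spec.n_genes, size=spec.n_driver_genes, replace=False)
    is_driver = np.zeros(spec.n_genes, dtype=bool)
    is_driver[driver_idx] = True
    driver_genes = sorted(genes[i] for i in driver_idx)

    # ~35% OG, ~35% TSG, ~5% dual-role, ~25% canonical without a usable role
    roles: dict[str, str] = {}
    role_choices = ["OG", "TSG", "both", "none"]
    role_probs = np.array([0.35, 0.35, 0.05, 0.25])
    for g in driver_genes:
        r = role_choices[rng.choice(4, p=role_probs)]
        if r != "none":
            roles[g] = r

    non_drivers = [g for g in sorted(genes) if g not in set(driver_genes)]
    picked = rng.choice(len(non_drivers), size=spec.n_candidate_genes + spec.n_false_positive_genes, replace=False)
    candidates = {non_drivers[i] for i in picked[: spec.n_candidate_genes]}
    false_positives = {non_drivers[i] for i in picked[spec.n_candidate_genes:]}

    properties = _gene_properties(genes, is_driver, spec, rng)
    properties = properties.sort_values("gene", kind="mergesort").reset_index(drop=True)

    weights = np.ones(spec.n_genes)
    weights[driver_idx] = spec.driver_rate_multiplier
    pmut = weights / weights.sum()

    mut_rows: list[dict] = []
    cnv_rows: list[dict] = []
    ploidy_rows: list[dict] = []
    swidth = len(str(spec.n_samples))
    for i in range(spec.n_samples):
        sid = f"S{i + 1:0{swidth}d}"
        ploidy = float(np.clip(rng.normal(2.7, 0.5), 1.5, 5.0))
        ploidy_rows.append({"sample": sid, "ploidy": round(ploidy, 3)})

        n_mut = int(np.clip(np.round(rng.lognormal(np.log(spec.mean_mut_genes), 0.4)), 3, spec.n_genes // 2))
        hit = rng.choice(spec.n_genes, size=n_mut, replace=False, p=pmut)
        for gi in sorted(hit):
            gene = genes[gi]
            role = roles.get(gene) if is_driver[gi] else None
            n_records = 1 + rng.poisson(0.3)
            mut_rows.append({"sample": sid, "gene": gene, **_damaging_record(role, rng)})
            for _ in range(n_records - 1):
                extra_role = role if rng.random() < 0.7 else None
                mut_rows.append({"sample": sid, "gene": gene, **_damaging_record(extra_role, rng)})

        # background of non-damaging records: exercised by the damaged filter
        n_bg = rng.poisson(8)
        bg = rng.choice(spec.n_genes, size=min(n_bg, spec.n_genes), replace=False)
        for gi in sorted(bg):
            vc = "synonymous" if rng.random() < 0.7 else "other"
            mut_rows.append(
                {"sample": sid, "gene": genes[gi], "variant_class": vc, "damaging_flag": False, "hotspot_flag": False}
            )

        n_cnv = rng.poisson(spec.mean_cnv_genes)
        cnv_hit = rng.choice(spec.n_genes, size=min(n_cnv, spec.n_genes), replace=False, p=pmut)
        for gi in sorted(cnv_hit):
            gene = genes[gi]
            role = roles.get(gene) if is_driver[gi] else None
            if role == "both":
                role = "OG" if rng.random() < 0.5 else "TSG"
            if role == "OG":
                amplify = True
            elif role == "TSG":
                amplify = False
            else:
                amplify = bool(rng.random() < 0.5)
            cn = ploidy * rng.uniform(2.0, 4.0) if amplify else float(rng.uniform(0.0, 0.9))
            cnv_rows.append({"sample": sid, "gene": gene, "copy_number": round(cn, 3)})
        # copy-neutral records for a few genes: should never call damage
        for gi in sorted(rng.choice(spec.n_genes, size=3, replace=False)):
            cnv_rows.append(
                {"sample": sid, "gene": genes[gi], "copy_number": round(ploidy * rng.uniform(0.8, 1.2), 3)}
            )

    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "variant_class", "damaging_flag", "hotspot_flag"])
    cnvs = (
        pd.DataFrame(cnv_rows, columns=["sample", "gene", "copy_number"])
        .drop_duplicates(subset=["sample", "gene"], keep="first")
        .reset_index(drop=True)
    )
    ploidy_df = pd.DataFrame(ploidy_rows, columns=["sample", "ploidy"])

    annotation = GeneAnnotation(
        canonical_roles={g: roles.get(g) for g in driver_genes},
        candidates=candidates,
        false_positives=false_positives,
    )
    return FixtureCohort(
        mutations=mutations,
        cnvs=cnvs,
        ploidy=ploidy_df,
        properties=properties,
        annotation=annotation,
        driver_genes=driver_genes,
        driver_roles=roles,
    )
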