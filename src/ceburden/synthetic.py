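"""Synthetic cohort, qPCR, proteome and knockdown-proteome generators.

Every downstream stage of the pipeline is testable without access to human
tissue data: the generators here emulate the study design — a postmortem
cohort spanning Control / LATE / AD / AD+LATE neuropathology, an 8-assay
cryptic-exon (CE) qPCR panel with housekeeping controls, a TMT-style
multi-batch proteome with internal reference (GIS) channels, and a small
two-group TDP-43-knockdown neuronal proteome — while recording the ground
truth (latent CE burden, subtype labels, module memberships, covariate
coefficients, concordant-effect sets) needed for parameter-recovery tests.

The generative model: each subject carries a latent CE burden drawn from a
3-component Gaussian mixture whose weights depend on pathology group (AD+LATE
skewed high, Control/AD mostly low, LATE mixed).  CE qPCR cycle thresholds
decrease with burden (more template amplifies earlier); proteome features
load on module factors that may themselves track burden; knockdown effects
are planted with signs matching the tissue-side burden loadings for the
concordant set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import AbundanceMatrix

GROUPS = ("Control", "LATE", "AD", "AD+LATE")

#: The eight cryptic-exon qPCR assays of the panel.
CE_ASSAYS = ("STMN2", "UNC13A", "ELAVL3", "KALRN", "ARHGAP32", "CAMK2B", "PFKP", "SYT7")

#: Housekeeping normalisation assays.
HK_ASSAYS = ("RPLP0", "GAPDH", "CYC1")

#: Cohort composition emulated by default (n=90 after outlier removal):
#: Control 21, LATE 10, AD 24, AD+LATE 35.
DEFAULT_PROPORTIONS = {"Control": 21 / 90, "LATE": 10 / 90, "AD": 24 / 90, "AD+LATE": 35 / 90}

#: Mixture weights over (low, intermediate, high) burden components per group.
GROUP_COMPONENT_WEIGHTS = {
    "Control": (0.85, 0.12, 0.03),
    "AD": (0.80, 0.15, 0.05),
    "LATE": (0.30, 0.40, 0.30),
    "AD+LATE": (0.10, 0.30, 0.60),
}

SUBTYPE_NAMES = ("low", "intermediate", "high")


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators for recovery tests."""

    latent_burden: pd.Series
    true_subtype: pd.Series
    subtype_thresholds: tuple[float, float]
    component: pd.Series
    #: per-feature frame (module, burden_loading, ce_gene, concordant,
    #: kd_log2fc) — populated by generate_proteome / generate_kd_proteome.
    features: pd.DataFrame | None = None
    #: per-feature covariate coefficients used by generate_proteome.
    covariate_effects: pd.DataFrame | None = None

    @property
    def module_membership(self) -> pd.Series:
        if self.features is None:
            raise ValueError("no proteome has been generated yet")
        return self.features["module"]

    @property
    def concordant_set(self) -> pd.Series:
        if self.features is None:
            raise ValueError("no proteome has been generated yet")
        return self.features["concordant"]

    @property
    def ce_gene_flags(self) -> pd.Series:
        if self.features is None:
            raise ValueError("no proteome has been generated yet")
        return self.features["ce_gene"]

    def to_json(self, path) -> None:
        payload = {
            "latent_burden": self.latent_burden.round(6).to_dict(),
            "true_subtype": self.true_subtype.to_dict(),
            "subtype_thresholds": list(self.subtype_thresholds),
            "component": self.component.astype(int).to_dict(),
        }
        if self.features is not None:
            payload["features"] = {
                col: self.features[col].to_dict() for col in self.features.columns
            }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class AssayParams:
    """Forward model of the qPCR readout.

    Ct[i, c] = ce_baseline + hk_shift_i - loading_c * burden_i + noise.
    Lower Ct means more template.  Housekeeping Cts share the per-subject
    shift but are independent of burden.
    """

    ce_assays: tuple[str, ...] = CE_ASSAYS
    hk_assays: tuple[str, ...] = HK_ASSAYS
    loadings: dict[str, float] | float = 1.0
    noise_sd: float = 0.25
    ce_baseline: float = 28.0
    hk_mean: float = 19.0
    hk_sd: float = 0.15
    subject_shift_sd: float = 0.3

    def loading_of(self, assay: str) -> float:
        if isinstance(self.loadings, dict):
            return float(self.loadings.get(assay, 0.0))
        return float(self.loadings)


@dataclass
class ModuleSpec:
    """Planted structure of the tissue proteome factor model.

    Module features: value = loading * factor_m + sqrt(1-loading^2) * eps,
    where factor_m = assoc_m * z(burden) + sqrt(1-assoc^2) * common noise.
    CE-gene and concordant features load directly on z(burden).  Covariate
    effects (age, sex, PMI, batch) and an additive per-sample shift are
    layered on top, and reference (GIS) channels carry batch effects only.
    """

    n_features: int = 1500
    module_sizes: tuple[int, ...] = (100, 80, 70, 50, 40, 30)
    intra_loading: float = 0.6
    burden_assoc: tuple[float, ...] = (0.6, -0.6, 0.0, 0.0, 0.4, 0.0)
    noise_sd: float = 1.0
    # CE-transcript features (direct burden loadings; mostly negative —
    # CE-bearing transcripts are typically degraded, depleting the protein)
    n_ce_negative: int = 30
    n_ce_positive: int = 5
    ce_loading: float = 0.7
    # concordant features planted in both tissue and knockdown arms
    n_concordant_down: int = 60
    n_concordant_up: int = 40
    concordant_loading: float = 0.6
    # covariate effect scales (per-feature coefficients ~ N(0, scale))
    age_slope_sd: float = 0.01
    sex_effect_sd: float = 0.15
    pmi_slope_sd: float = 0.02
    batch_offset_sd: float = 0.3
    # optional fixed overrides applied to every feature (for recovery tests)
    fixed_batch_offset: dict | None = None
    fixed_age_slope: float | None = None
    fixed_group_effect: dict | None = None
    # missingness; MNAR steepness reflects detection-limit censoring (only
    # genuinely low-intensity cells go missing)
    mcar_rate: float = 0.05
    mnar_rate: float = 0.05
    mnar_steepness: float = 4.0
    n_reference_per_batch: int = 2
    reference_noise_sd: float = 0.05


@dataclass
class EffectSpec:
    """Planted effects for the knockdown-vs-control neuronal proteome."""

    effect_size: float = 3.0  # |log2FC|; TDP-43-dependent losses are near-complete
    noise_sd: float = 0.3
    missing_rate: float = 0.05
    mnar_steepness: float = 4.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    #: technical replicate injections per biological sample; replicates are
    #: averaged before imputation in the analysis arm
    n_replicates: int = 2
    replicate_noise_sd: float = 0.15
    #: explicit per-feature log2FC overrides (feature -> log2FC)
    log2fc_overrides: dict | None = None


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(
    n_subjects: int = 90,
    group_proportions: dict[str, float] | None = None,
    seed: int = 0,
    separation_sd: float = 2.0,
    component_sd: float = 1.0,
    ptdp43_burden_corr: float = 0.6,
    mmse_slope: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate subject metadata, trait immunoassays and the latent burden.

    Latent CE burden is drawn from a 3-component Gaussian mixture (component
    means 0, separation_sd, 2*separation_sd; within-component SD
    ``component_sd``) with group-dependent weights.  True subtype labels are
    assigned by thresholding the burden at the midpoints between adjacent
    component means.  pTDP-43 rises with burden (correlation configurable —
    the two are related but not co-dependent); pTau ratio and Abeta42 are
    elevated in AD-containing groups independent of burden; MMSE declines
    with burden.

    Returns ``(meta, traits, ground_truth)``.
    """
    if n_subjects < 12:
        raise ValueError("n_subjects must be at least 12")
    props = dict(group_proportions or DEFAULT_PROPORTIONS)
    unknown = set(props) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    total = sum(props.values())
    if not np.isclose(total, 1.0, atol=1e-6) or any(v < 0 for v in props.values()):
        raise ValueError(f"group proportions must be nonnegative and sum to 1 (got {total:g})")

    rng = np.random.default_rng(seed)
    # deterministic counts by largest remainder, then shuffled assignment
    labels = [g for g in GROUPS if props.get(g, 0) > 0]
    raw = np.array([props[g] * n_subjects for g in labels])
    counts = np.floor(raw).astype(int)
    rem = n_subjects - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    group = np.repeat(labels, counts)
    rng.shuffle(group)

    subject_id = [f"S{i + 1:03d}" for i in range(n_subjects)]
    means = np.array([0.0, separation_sd, 2.0 * separation_sd]) * component_sd
    comp = np.array(
        [rng.choice(3, p=GROUP_COMPONENT_WEIGHTS[g]) for g in group]
    )
    burden = means[comp] + component_sd * rng.normal(size=n_subjects)
    thresholds = (float((means[0] + means[1]) / 2), float((means[1] + means[2]) / 2))
    subtype = np.where(
        burden < thresholds[0], "low", np.where(burden < thresholds[1], "intermediate", "high")
    )

    age = np.clip(rng.normal(80.0, 8.0, n_subjects), 55.0, 100.0).round(1)
    sex = rng.choice(["F", "M"], n_subjects)
    pmi = np.clip(rng.gamma(4.0, 2.0, n_subjects), 1.0, None).round(1)
    # randomized into 6 batches; two GIS channels per batch are added when the
    # proteome is generated
    n_batches = 6
    batch = np.array([f"b{(i % n_batches) + 1}" for i in range(n_subjects)])
    rng.shuffle(batch)
    channel = np.array(
        [f"ch{np.sum(batch[: i + 1] == batch[i]):02d}" for i in range(n_subjects)]
    )
    zb = (burden - burden.mean()) / (burden.std() or 1.0)
    mmse = np.clip(28.0 - mmse_slope * zb + rng.normal(0, 1.5, n_subjects), 0, 30).round(0)

    meta = pd.DataFrame(
        {
            "group": group,
            "age": age,
            "sex": sex,
            "pmi": pmi,
            "batch": batch,
            "channel": channel,
            "mmse": mmse,
        },
        index=pd.Index(subject_id, name="subject_id"),
    )

    # traits: pTDP-43 on an immunoassay scale, correlated with burden but not
    # identical to it; a small fraction falls below detection (NaN)
    r = ptdp43_burden_corr
    z = r * zb + np.sqrt(max(1.0 - r**2, 0.0)) * rng.normal(size=n_subjects)
    ptdp43 = np.round(np.exp(0.8 * z + 0.2), 3)
    below = rng.random(n_subjects) < 0.08
    ptdp43 = np.where(below, np.nan, ptdp43)
    is_ad = np.isin(group, ["AD", "AD+LATE"]).astype(float)
    ptau_ratio = np.round(0.5 + 1.2 * is_ad + rng.normal(0, 0.4, n_subjects), 3)
    abeta42 = np.round(-1.0 * is_ad + rng.normal(0, 0.5, n_subjects), 3)
    traits = pd.DataFrame(
        {"ptdp43": ptdp43, "ptau_ratio": ptau_ratio, "abeta42": abeta42},
        index=meta.index,
    )

    gt = GroundTruth(
        latent_burden=pd.Series(burden, index=meta.index, name="latent_burden"),
        true_subtype=pd.Series(subtype, index=meta.index, name="true_subtype"),
        subtype_thresholds=thresholds,
        component=pd.Series(comp, index=meta.index, name="component"),
    )
    return meta, traits, gt


# ---------------------------------------------------------------------------
# qPCR cycle thresholds
# ---------------------------------------------------------------------------


def generate_ct_table(
    meta: pd.DataFrame,
    ground_truth: GroundTruth,
    assay_params: AssayParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the raw qPCR Ct table (subjects x [CE assays + housekeeping]).

    More CE expression amplifies earlier, so Ct decreases with latent burden:
    Ct[i,c] = ce_baseline + shift_i - loading_c * centered_burden_i + noise.
    Housekeeping Cts carry the per-subject shift but no burden term, so the
    delta-Ct transform recovers (minus) the burden signal.
    """
    ap = assay_params or AssayParams()
    if ap.noise_sd < 0 or ap.hk_sd < 0:
        raise ValueError("noise SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    burden = ground_truth.latent_burden.reindex(meta.index).to_numpy()
    centered = burden - burden.mean()
    n = len(meta)
    shift = ap.subject_shift_sd * rng.normal(size=n)
    cols = {}
    for assay in ap.ce_assays:
        cols[assay] = (
            ap.ce_baseline
            + shift
            - ap.loading_of(assay) * centered
            + ap.noise_sd * rng.normal(size=n)
        )
    for hk in ap.hk_assays:
        cols[hk] = ap.hk_mean + shift + ap.hk_sd * rng.normal(size=n)
    ct = pd.DataFrame(cols, index=meta.index)
    if (ct.to_numpy() <= 0).any():
        raise ValueError("simulated Ct values must be positive; lower the loadings or noise")
    return ct


# ---------------------------------------------------------------------------
# tissue proteome
# ---------------------------------------------------------------------------


def generate_proteome(
    meta: pd.DataFrame,
    ground_truth: GroundTruth,
    module_spec: ModuleSpec | None = None,
    seed: int = 0,
) -> AbundanceMatrix:
    """Simulate the multi-batch TMT-style tissue proteome.

    Features x samples log2 abundance with planted module factor structure,
    burden-loaded CE-gene and concordant features, per-feature covariate
    effects (age, sex, PMI, batch), per-sample loading offsets, reference
    (GIS) channels per batch, and MCAR + intensity-dependent MNAR
    missingness.  Ground truth is recorded on ``ground_truth.features`` /
    ``ground_truth.covariate_effects``.
    """
    ms = module_spec or ModuleSpec()
    n_special = ms.n_ce_negative + ms.n_ce_positive + ms.n_concordant_down + ms.n_concordant_up
    if sum(ms.module_sizes) + n_special > ms.n_features:
        raise ValueError(
            f"module sizes ({sum(ms.module_sizes)}) plus planted features ({n_special}) "
            f"exceed n_features ({ms.n_features})"
        )
    if len(ms.burden_assoc) != len(ms.module_sizes):
        raise ValueError("burden_assoc must have one entry per module")
    rng = np.random.default_rng(seed)
    n = len(meta)
    burden = ground_truth.latent_burden.reindex(meta.index).to_numpy()
    zb = (burden - burden.mean()) / (burden.std() or 1.0)

    features = pd.Index([f"P{i + 1:05d}" for i in range(ms.n_features)], name="feature")
    module = np.zeros(ms.n_features, dtype=int)
    direct_loading = np.zeros(ms.n_features)
    ce_gene = np.zeros(ms.n_features, dtype=bool)
    concordant = np.array(["none"] * ms.n_features, dtype=object)

    pos = 0
    for m, size in enumerate(ms.module_sizes, start=1):
        module[pos : pos + size] = m
        pos += size
    ce_neg = slice(pos, pos + ms.n_ce_negative)
    pos += ms.n_ce_negative
    ce_pos = slice(pos, pos + ms.n_ce_positive)
    pos += ms.n_ce_positive
    con_dn = slice(pos, pos + ms.n_concordant_down)
    pos += ms.n_concordant_down
    con_up = slice(pos, pos + ms.n_concordant_up)
    pos += ms.n_concordant_up
    ce_gene[ce_neg] = ce_gene[ce_pos] = True
    direct_loading[ce_neg] = -ms.ce_loading
    direct_loading[ce_pos] = ms.ce_loading
    direct_loading[con_dn] = -ms.concordant_loading
    direct_loading[con_up] = ms.concordant_loading
    concordant[con_dn] = "down"
    concordant[con_up] = "up"

    baseline = rng.normal(0.0, 1.0, ms.n_features)

    # module factors: correlated with burden per assoc, shared sample noise
    signal = np.zeros((ms.n_features, n))
    for m, assoc in enumerate(ms.burden_assoc, start=1):
        idx = module == m
        factor = assoc * zb + np.sqrt(max(1 - assoc**2, 0.0)) * rng.normal(size=n)
        lam = ms.intra_loading
        eps = rng.normal(size=(idx.sum(), n))
        signal[idx] = lam * factor + np.sqrt(max(1 - lam**2, 0.0)) * eps
    bg = module == 0
    lam_bg = np.abs(direct_loading[bg])[:, None]
    sign_bg = np.sign(direct_loading[bg])[:, None]
    signal[bg] = sign_bg * lam_bg * zb + np.sqrt(np.maximum(1 - lam_bg**2, 0.0)) * rng.normal(
        size=(bg.sum(), n)
    )

    # covariate effects
    cov = pd.DataFrame(
        {
            "age": rng.normal(0, ms.age_slope_sd, ms.n_features),
            "sex_M": rng.normal(0, ms.sex_effect_sd, ms.n_features),
            "pmi": rng.normal(0, ms.pmi_slope_sd, ms.n_features),
        },
        index=features,
    )
    if ms.fixed_age_slope is not None:
        cov["age"] = ms.fixed_age_slope
    batches = sorted(meta["batch"].unique())
    batch_eff = {}
    for b in batches:
        off = rng.normal(0, ms.batch_offset_sd, ms.n_features)
        if ms.fixed_batch_offset and b in ms.fixed_batch_offset:
            off = np.full(ms.n_features, float(ms.fixed_batch_offset[b]))
        batch_eff[b] = off
        cov[f"batch_{b}"] = off

    age_c = meta["age"].to_numpy() - meta["age"].mean()
    pmi_c = meta["pmi"].to_numpy() - meta["pmi"].mean()
    is_m = (meta["sex"] == "M").to_numpy(dtype=float)
    covariate_part = (
        np.outer(cov["age"].to_numpy(), age_c)
        + np.outer(cov["sex_M"].to_numpy(), is_m)
        + np.outer(cov["pmi"].to_numpy(), pmi_c)
    )
    batch_part = np.column_stack([batch_eff[b] for b in meta["batch"]])
    group_part = np.zeros((ms.n_features, n))
    if ms.fixed_group_effect:
        for g, eff in ms.fixed_group_effect.items():
            group_part[:, (meta["group"] == g).to_numpy()] = float(eff)

    values = (
        baseline[:, None]
        + signal * ms.noise_sd
        + covariate_part
        + batch_part
        + group_part
    )

    # reference (GIS) channels: batch effect + baseline, tiny noise
    gis_cols, gis_vals = [], []
    for b in batches:
        for k in range(ms.n_reference_per_batch):
            gis_cols.append(f"GIS_{b}_{k + 1}")
            gis_vals.append(
                baseline + batch_eff[b] + ms.reference_noise_sd * rng.normal(size=ms.n_features)
            )
    all_values = np.column_stack([values] + [v[:, None] for v in gis_vals])
    columns = list(meta.index) + gis_cols

    # missingness: MCAR plus intensity-dependent MNAR (low values more likely
    # missing); reference channels are spared the MNAR term's burden signal
    if ms.mcar_rate or ms.mnar_rate:
        mu, sd = all_values.mean(), all_values.std() or 1.0
        z = (all_values - mu) / sd
        p_miss = ms.mcar_rate + ms.mnar_rate * 2.0 * expit(-ms.mnar_steepness * z)
        mask = rng.random(all_values.shape) < np.clip(p_miss, 0, 0.95)
        all_values = np.where(mask, np.nan, all_values)

    annot = pd.DataFrame(
        {
            "batch": list(meta["batch"]) + [c.split("_")[1] for c in gis_cols],
            "is_reference": [False] * n + [True] * len(gis_cols),
            "group": list(meta["group"]) + [""] * len(gis_cols),
        },
        index=pd.Index(columns, name="sample_id"),
    )
    mat = AbundanceMatrix(
        pd.DataFrame(all_values, index=features, columns=columns), annot
    )

    ground_truth.features = pd.DataFrame(
        {
            "module": module,
            "burden_loading": direct_loading,
            "ce_gene": ce_gene,
            "concordant": concordant,
        },
        index=features,
    )
    ground_truth.covariate_effects = cov
    return mat


# ---------------------------------------------------------------------------
# knockdown proteome
# ---------------------------------------------------------------------------


def generate_kd_proteome(
    ground_truth: GroundTruth,
    effect_spec: EffectSpec | None = None,
    n_per_group: int = 4,
    seed: int = 0,
) -> AbundanceMatrix:
    """Simulate the TDP-43-knockdown vs control neuronal proteome.

    Two groups of ``n_per_group`` samples; features planted as concordant in
    the tissue arm receive a knockdown log2FC of the matching sign, so the
    cross-modal concordance classes are recoverable.  Missing values are
    MNAR-flavoured (preferentially low) to exercise downshifted imputation.
    """
    es = effect_spec or EffectSpec()
    if n_per_group < 2:
        raise ValueError("n_per_group must be at least 2 (t-test undefined below)")
    if ground_truth.features is None:
        raise ValueError("generate_proteome must be called first to define the feature set")
    rng = np.random.default_rng(seed)
    feats = ground_truth.features
    nf = len(feats)
    log2fc = np.where(
        feats["concordant"] == "down",
        -es.effect_size,
        np.where(feats["concordant"] == "up", es.effect_size, 0.0),
    ).astype(float)
    if es.log2fc_overrides:
        for f, v in es.log2fc_overrides.items():
            log2fc[feats.index.get_loc(f)] = float(v)
    ground_truth.features = feats.assign(kd_log2fc=log2fc)

    base = rng.normal(es.baseline_mean, es.baseline_sd, nf)
    ctrl = base[:, None] + es.noise_sd * rng.normal(size=(nf, n_per_group))
    kd = (base + log2fc)[:, None] + es.noise_sd * rng.normal(size=(nf, n_per_group))
    samples = np.column_stack([ctrl, kd])
    sample_ids = [f"ctrl_{i + 1}" for i in range(n_per_group)] + [
        f"kd_{i + 1}" for i in range(n_per_group)
    ]
    groups = ["control"] * n_per_group + ["kd"] * n_per_group
    # technical replicate injections of each sample
    nrep = max(int(es.n_replicates), 1)
    cols, col_sample, col_group = [], [], []
    reps = []
    for j, sid in enumerate(sample_ids):
        for r in range(nrep):
            cols.append(f"{sid}_r{r + 1}" if nrep > 1 else sid)
            col_sample.append(sid)
            col_group.append(groups[j])
            reps.append(
                samples[:, j] + es.replicate_noise_sd * rng.normal(size=nf)
            )
    values = np.column_stack(reps)
    if es.missing_rate:
        z = (values - values.mean()) / (values.std() or 1.0)
        p = np.clip(es.missing_rate * 2.0 * expit(-es.mnar_steepness * z), 0, 0.9)
        values = np.where(rng.random(values.shape) < p, np.nan, values)
    annot = pd.DataFrame(
        {"group": col_group, "sample": col_sample},
        index=pd.Index(cols, name="sample_id"),
    )
    return AbundanceMatrix(pd.DataFrame(values, index=feats.index, columns=cols), annot)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_simulation(
    outdir,
    meta: pd.DataFrame,
    traits: pd.DataFrame,
    ground_truth: GroundTruth,
    ct_table: pd.DataFrame | None = None,
    proteome: AbundanceMatrix | None = None,
    kd_proteome: AbundanceMatrix | None = None,
) -> None:
    """Write all simulated tables as TSV plus the ground-truth JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "meta.tsv", sep="\t")
    traits.to_csv(out / "traits.tsv", sep="\t")
    ground_truth.to_json(out / "ground_truth.json")
    if ct_table is not None:
        ct_table.to_csv(out / "ct_table.tsv", sep="\t")
    if proteome is not None:
        proteome.write(out / "proteome.tsv", out / "proteome_samples.tsv")
    if kd_proteome is not None:
        kd_proteome.write(out / "kd_proteome.tsv", out / "kd_samples.tsv")
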