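"""Synthetic paired pre/post expression studies with planted structure.

The generator emulates the study design this pipeline targets: ~16
subjects sampled before an endurance race and a subset of them again
after it, a continuous completed-distance covariate (drawn from the
observed 14-82 km race distances), a binary gender covariate, gene-wise
residual variances from a scaled inverse-chi-square prior, a sparse set
of true per-km distance effects (mostly down-regulated, 63:37), and a
small number of planted latent expression modes with super-Gaussian
(Laplace) activations so that ICA identifiability holds.  Annotation
databases with terms oversampling the planted differential genes give
the enrichment stage known positives.

All randomness flows from a single seed through one named generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import (
    DataError,
    ExpressionMatrix,
    FeatureAnnotation,
    GeneSet,
    GeneSetDB,
    SampleInfo,
    TrTargetDB,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_dataset", "simulate_databases"]

# completed distances (km) observed in the emulated race design
DEFAULT_DISTANCES_KM = (82, 82, 50, 50, 25, 42, 50, 82, 58, 25, 33, 50, 28, 50, 14)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_genes: int = 2000
    n_subjects: int = 16
    post_fraction: float = 0.75          # 12 of 16 subjects have a post sample
    distances_km: tuple = DEFAULT_DISTANCES_KM
    gender_ratio: float = 0.5            # fraction male
    pi_diff: float = 0.10                # fraction of true distance-responsive genes
    effect_floor_snr: float = 3.0        # min |beta2|*d_ref in units of the gene's noise SD
    effect_excess_snr: float = 1.0       # mean of the exponential excess above the floor
    down_fraction: float = 0.63          # sign split of true effects
    pi_gender: float = 0.02              # fraction of true gender effects
    gender_effect_sd: float = 0.5        # log2 units
    d0: float = 4.0                      # variance prior df
    s0_squared: float = 0.05             # variance prior scale
    k_modes: int = 3
    mode_source: str = "laplace"         # "gaussian" only for negative controls
    mode_sparsity: float = 0.10          # fraction of genes loaded per mode (decile-sized modules)
    mode_amplitude: float = 1.5          # log2 scale of mode weights
    dominant_mode_scale: float = 5.0     # multiplier making mode 1 the masking signal
    subject_sd: float = 0.2              # shared subject baseline SD (log2)
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    multi_fraction: float = 0.05         # features annotated to >1 gene
    unannotated_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("post_fraction", "gender_ratio", "pi_diff", "down_fraction",
                     "pi_gender", "mode_sparsity", "multi_fraction",
                     "unannotated_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must lie in [0, 1], got {v}")
        if self.d0 <= 0 or self.s0_squared <= 0:
            raise DataError("variance prior needs d0 > 0 and s0_squared > 0")
        if self.mode_source not in ("laplace", "gaussian"):
            raise DataError(f"unknown mode source {self.mode_source!r}")
        if self.n_genes < 20 or self.n_subjects < 4:
            raise DataError("simulation needs n_genes >= 20 and n_subjects >= 4")


@dataclass
class GroundTruth:
    """Everything planted, for downstream recovery checks."""

    feature_ids: list[str]
    gene_map: dict[str, list[str]]         # feature -> gene ids
    genes: list[str]                       # distinct single-annotation genes
    beta1: np.ndarray                      # (n,) true gender effects
    beta2: np.ndarray                      # (n,) true per-km distance effects
    diff_features: list[str]               # features with beta2 != 0
    diff_genes: set[str]
    variances: np.ndarray                  # (n,) residual variances
    mode_weights: np.ndarray               # (k, n) gene weights per planted mode
    mode_activations: np.ndarray           # (m, k) sample activations
    mode_feature_sets: list[set[str]]      # features loaded per mode
    mode_gene_sets: list[set[str]]         # genes loaded per mode
    enriched_terms: list[str] = field(default_factory=list)
    enriched_regulators: list[str] = field(default_factory=list)

    def regulation_map(self) -> dict[str, str]:
        reg: dict[str, str] = {}
        for feat, b2 in zip(self.feature_ids, self.beta2):
            genes = self.gene_map.get(feat, [])
            if b2 != 0 and len(genes) == 1:
                reg[genes[0]] = "down" if b2 < 0 else "up"
        return reg


def _annotate(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    """Assign features to genes: mostly 1:1, some multi, some unannotated."""
    feature_ids = [f"TC{i:06d}" for i in range(n)]
    roles = np.full(n, "single", dtype=object)
    n_multi = int(round(cfg.multi_fraction * n))
    n_unann = int(round(cfg.unannotated_fraction * n))
    special = rng.choice(n, size=n_multi + n_unann, replace=False)
    roles[special[:n_multi]] = "multi"
    roles[special[n_multi:]] = "none"
    gene_map: dict[str, list[str]] = {}
    gene_counter = 0
    for feat, role in zip(feature_ids, roles):
        if role == "none":
            gene_map[feat] = []
        elif role == "multi":
            gene_map[feat] = [f"G{gene_counter:06d}", f"G{gene_counter + 1:06d}"]
            gene_counter += 2
        else:
            gene_map[feat] = [f"G{gene_counter:06d}"]
            gene_counter += 1
    return feature_ids, gene_map, roles


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, FeatureAnnotation, GroundTruth]:
    """Generate one paired pre/post study with planted effects and modes.

    Expression is gene baseline + shared subject baseline + beta1*g +
    beta2*d + sum of mode weight x activation + Gaussian noise whose
    gene-wise variance is drawn from s0^2 * d0 / chi2_d0.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes

    # --- samples -------------------------------------------------------
    n_post = int(round(cfg.post_fraction * cfg.n_subjects))
    post_subjects = set(rng.choice(cfg.n_subjects, size=n_post, replace=False))
    genders = np.array(["male"] * cfg.n_subjects, dtype=object)
    n_male = int(round(cfg.gender_ratio * cfg.n_subjects))
    female_idx = rng.choice(cfg.n_subjects, size=cfg.n_subjects - n_male, replace=False)
    genders[female_idx] = "female"
    distances = rng.choice(np.asarray(cfg.distances_km, dtype=float),
                           size=cfg.n_subjects, replace=True)
    samples: list[SampleInfo] = []
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:02d}"
        samples.append(SampleInfo(f"{sid}_PRE", sid, "pre", genders[s], 0.0))
        if s in post_subjects:
            samples.append(
                SampleInfo(f"{sid}_POST", sid, "post", genders[s], float(distances[s]))
            )
    m = len(samples)
    g = np.array([1.0 if s.gender == "male" else 0.0 for s in samples])
    d = np.array([s.distance_km for s in samples])

    # --- annotation ----------------------------------------------------
    feature_ids, gene_map, roles = _annotate(rng, n, cfg)
    single_mask = roles == "single"

    # --- gene-wise residual variances (scaled inverse-chi-square) ------
    variances = cfg.s0_squared * cfg.d0 / rng.chisquare(cfg.d0, size=n)

    # --- latent modes --------------------------------------------------
    k = cfg.k_modes
    weights = np.zeros((max(k, 1), n))[:k]
    activations = np.zeros((m, max(k, 1)))[:, :k]
    mode_feature_sets: list[set[str]] = []
    for j in range(k):
        n_loaded = max(2, int(round(cfg.mode_sparsity * n)))
        loaded = rng.choice(n, size=n_loaded, replace=False)
        w = np.zeros(n)
        w[loaded] = rng.normal(0.0, cfg.mode_amplitude, n_loaded)
        if j == 0:
            w *= cfg.dominant_mode_scale
        weights[j] = w
        if cfg.mode_source == "laplace":
            activations[:, j] = rng.laplace(0.0, 1.0 / np.sqrt(2.0), m)
        else:
            activations[:, j] = rng.normal(0.0, 1.0, m)
        mode_feature_sets.append({feature_ids[i] for i in loaded})
    mode_loaded = np.flatnonzero(np.any(weights != 0, axis=0)) if k else np.array([], int)

    # --- planted effects (on single-annotation, mode-free features) ----
    # magnitudes are anchored to each gene's own noise SD: at the
    # reference distance (mean completed km) the expression shift is at
    # least effect_floor_snr noise SDs.  Effects are planted on genes
    # carrying no mode loading so that each planted structure is
    # attributable to exactly one mechanism.
    beta2 = np.zeros(n)
    n_diff = int(round(cfg.pi_diff * n))
    single_idx = np.setdiff1d(np.flatnonzero(single_mask), mode_loaded)
    diff_idx = rng.choice(single_idx, size=min(n_diff, single_idx.size), replace=False)
    d_ref = float(np.mean(cfg.distances_km))
    snr = cfg.effect_floor_snr + rng.exponential(cfg.effect_excess_snr, diff_idx.size)
    magnitudes = snr * np.sqrt(variances[diff_idx]) / d_ref
    signs = np.where(rng.random(diff_idx.size) < cfg.down_fraction, -1.0, 1.0)
    beta2[diff_idx] = signs * magnitudes

    beta1 = np.zeros(n)
    n_gender = int(round(cfg.pi_gender * n))
    if n_gender:
        pool = np.setdiff1d(single_idx, diff_idx)
        gender_idx = rng.choice(pool, size=min(n_gender, pool.size), replace=False)
        beta1[gender_idx] = rng.normal(0.0, cfg.gender_effect_sd, gender_idx.size)

    # --- assemble expression ------------------------------------------
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n)
    subj_index = {sid: i for i, sid in enumerate(
        dict.fromkeys(x.subject_id for x in samples))}
    subject_base = rng.normal(0.0, cfg.subject_sd, (len(subj_index), n))
    values = np.empty((n, m))
    noise = rng.normal(0.0, 1.0, (n, m)) * np.sqrt(variances)[:, None]
    for jcol, s in enumerate(samples):
        values[:, jcol] = (
            baseline
            + subject_base[subj_index[s.subject_id]]
            + beta1 * g[jcol]
            + beta2 * d[jcol]
            + weights.T @ activations[jcol]
            + noise[:, jcol]
        )

    expr = ExpressionMatrix(feature_ids, samples, values)
    annotation = FeatureAnnotation(gene_map)
    genes = sorted({gs[0] for f, gs in gene_map.items() if len(gs) == 1})
    diff_features = [feature_ids[i] for i in sorted(diff_idx)]
    truth = GroundTruth(
        feature_ids=feature_ids,
        gene_map=gene_map,
        genes=genes,
        beta1=beta1,
        beta2=beta2,
        diff_features=diff_features,
        diff_genes={gene_map[f][0] for f in diff_features},
        variances=variances,
        mode_weights=weights,
        mode_activations=activations,
        mode_feature_sets=mode_feature_sets,
        mode_gene_sets=[
            {gene_map[f][0] for f in fs if len(gene_map[f]) == 1}
            for fs in mode_feature_sets
        ],
    )
    return expr, annotation, truth


def _weighted_sample(rng, pool: np.ndarray, weights: np.ndarray, size: int):
    p = weights / weights.sum()
    return rng.choice(pool, size=size, replace=False, p=p)


def simulate_databases(
    truth: GroundTruth,
    n_terms: int = 300,
    term_size_range: tuple[int, int] = (20, 200),
    enrichment_odds: float = 10.0,
    n_enriched_terms: int = 5,
    n_regulators: int = 196,
    tr_universe_size: int | None = None,
    n_enriched_regulators: int = 5,
    enrich_mode_genes: int | None = None,
    seed: int = 0,
) -> tuple[GeneSetDB, TrTargetDB]:
    """Annotation databases with planted enriched terms.

    Most terms sample genes uniformly from the gene universe; the first
    ``n_enriched_terms`` oversample the true differential genes (or, when
    ``enrich_mode_genes`` names a planted mode, that mode's genes) at the
    stated odds.  The regulator database follows a 196-regulator layout
    whose target universe is padded with filler genes up to
    ``tr_universe_size`` so that every universe gene is a target of at
    least one regulator.
    """
    if enrichment_odds < 1:
        raise DataError("enrichment_odds must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.array(truth.genes, dtype=object)
    if enrich_mode_genes is None:
        favored = truth.diff_genes
    else:
        favored = truth.mode_gene_sets[enrich_mode_genes]
    fav_weight = np.where(np.isin(universe, sorted(favored)), enrichment_odds, 1.0)
    lo, hi = term_size_range
    if hi > universe.size:
        raise DataError(
            f"term size up to {hi} exceeds the {universe.size}-gene universe"
        )
    terms: list[GeneSet] = []
    enriched_ids: list[str] = []
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        if t < n_enriched_terms:
            members = _weighted_sample(rng, universe, fav_weight, size)
            enriched_ids.append(f"T{t:04d}")
        else:
            members = rng.choice(universe, size=size, replace=False)
        terms.append(
            GeneSet(f"T{t:04d}", f"synthetic term {t}", "synthetic",
                    frozenset(members.tolist()))
        )
    gsdb = GeneSetDB(terms)
    truth.enriched_terms = enriched_ids

    # --- regulator layout ---------------------------------------------
    if tr_universe_size is None:
        tr_universe_size = universe.size
    if tr_universe_size < universe.size:
        pool = universe[:tr_universe_size].copy()
    else:
        filler = np.array(
            [f"TG{i:06d}" for i in range(tr_universe_size - universe.size)],
            dtype=object,
        )
        pool = np.concatenate([universe, filler])
    pool_fav = np.where(np.isin(pool, sorted(favored)), enrichment_odds, 1.0)
    targets: dict[str, set[str]] = {f"TR{r:03d}": set() for r in range(n_regulators)}
    reg_ids = list(targets)
    # every pool gene is annotated to at least one regulator
    owner = rng.integers(0, n_regulators, size=pool.size)
    for gene, r in zip(pool, owner):
        targets[reg_ids[r]].add(gene)
    # target-set sizes span orders of magnitude (real regulator databases
    # range from tens of targets to a quarter of the universe)
    log_lo, log_hi = np.log10(0.005), np.log10(0.25)
    for i, reg in enumerate(reg_ids):
        frac = 10.0 ** rng.uniform(log_lo, log_hi)
        size = max(5, min(int(round(frac * pool.size)), pool.size))
        if i < n_enriched_regulators:
            extra = _weighted_sample(rng, pool, pool_fav, size)
        else:
            extra = rng.choice(pool, size=size, replace=False)
        targets[reg].update(extra.tolist())
    truth.enriched_regulators = reg_ids[:n_enriched_regulators]
    trdb = TrTargetDB([(r, frozenset(targets[r])) for r in reg_ids])
    return gsdb, trdb
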