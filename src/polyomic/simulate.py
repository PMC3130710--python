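"""Ground-truth generators for every layer of the pipeline.

The stated world mirrors a knockout-vs-wild-type liver study profiled on
three platforms:

* 8-channel iTRAQ runs (reporter channels 113-121) with one channel holding
  a pooled internal standard, seven samples per group, and each sample
  measured twice in independent runs under rotated channel assignments;
* a transcript matrix of ~34,273 features, five samples per group, with a
  small differentially expressed minority (~899 features by default);
* a plasma metabolite concentration table of 205 compounds, nine samples
  per group, on a strictly positive scale;
* GMT gene-set collections with a few sets planted to be over-represented
  among the differential features.

Every generator is a pure function of ``(config, seed)``: identical inputs
give byte-identical outputs.  Noise is multiplicative lognormal with a
configured coefficient of variation; ``noise_cv = 0`` yields exactly
noise-free tables, which downstream identity tests rely on.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .differential import GROUP_KO, GROUP_WT, ExpressionMatrix
from .errors import ConfigError

DEFAULT_CHANNELS = ("113", "114", "115", "116", "117", "118", "119", "121")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the stated world; defaults reproduce the study design."""

    # proteomics
    n_proteins: int = 200
    peptides_min: int = 2
    peptides_mean: float = 6.0
    extra_spectrum_prob: float = 0.25  # chance a peptide yields a 2nd spectrum
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    intensity_log_mean: float = 9.2  # ln scale, ~1e4 counts
    intensity_log_sd: float = 1.0
    noise_cv: float = 0.2
    outlier_fraction: float = 0.01
    max_channel_bias: float = 1.5
    n_per_group_protein: int = 7
    frac_de_protein: float = 0.15
    protein_effect_range: tuple[float, float] = (0.3, 2.5)  # |log2| effect
    # transcripts
    n_features_transcript: int = 34273
    n_per_group_transcript: int = 5
    frac_de: float = 899 / 34273
    effect_range: tuple[float, float] = (0.3, 2.5)
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    # metabolites
    n_features_metabolite: int = 205
    n_per_group_metabolite: int = 9
    frac_de_metabolite: float = 0.15
    metabolite_effect_range: tuple[float, float] = (0.4, 8.0)
    metabolite_noise_sd: float = 0.5  # log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_de_protein", "frac_de_metabolite",
                     "outlier_fraction", "extra_spectrum_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_proteins", "n_features_transcript", "n_features_metabolite",
                     "n_per_group_protein", "n_per_group_transcript",
                     "n_per_group_metabolite", "peptides_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if len(self.channel_labels) < 2:
            raise ConfigError("need at least 2 channels (reference + 1 sample)")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be non-negative")
        if self.max_channel_bias < 1.0:
            raise ConfigError("max_channel_bias must be >= 1")

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class SimTruth:
    """Everything the generators decided, for comparing estimates against.

    ``protein_log2_ratio`` is log2(sample abundance / pooled reference), one
    column per proteomic sample; the pooled reference is the unweighted mean
    of the per-sample abundances, mimicking an equal-mass internal standard.
    ``channel_bias`` is replicates x channel labels, multiplicative, with the
    internal-standard channel fixed at 1.0.
    """

    protein_log2_ratio: pd.DataFrame | None = None
    protein_de_flags: pd.Series | None = None
    channel_bias: pd.DataFrame | None = None
    de_flags: pd.Series | None = None
    effect_sizes: pd.Series | None = None
    feature_sigma2: pd.Series | None = None
    metabolite_de_flags: pd.Series | None = None
    metabolite_effects: pd.Series | None = None
    enriched_set_ids: list[str] = field(default_factory=list)


def _rng(config: SimConfig, *streams) -> np.random.Generator:
    ids = [config.seed] + [zlib.crc32(str(s).encode()) for s in streams]
    return np.random.default_rng(ids)


def _noise_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise; exactly 1.0 when cv == 0."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def protein_sample_ids(config: SimConfig) -> list[str]:
    k = config.n_per_group_protein
    return [f"KO{i+1:02d}" for i in range(k)] + [f"WT{i+1:02d}" for i in range(k)]


def make_protein_truth(
    config: SimConfig,
    replicates: tuple[str, ...] = ("A", "B"),
    effects: np.ndarray | None = None,
) -> SimTruth:
    """Per-protein per-sample true log2 ratios plus per-replicate channel bias.

    ``effects`` pins the per-protein log2 KO-vs-WT effects (e.g. to couple
    them to a transcript layer's truth); by default a ``frac_de_protein``
    minority gets random effects.
    """
    if config.n_proteins <= 0:
        raise ConfigError("n_proteins must be positive")
    rng = _rng(config, "protein-truth")
    proteins = [f"P{i+1:05d}" for i in range(config.n_proteins)]
    samples = protein_sample_ids(config)
    if effects is not None:
        effects = np.asarray(effects, dtype=float)
        if effects.shape != (config.n_proteins,):
            raise ConfigError("effects must have one entry per protein")
        de = effects != 0.0
    else:
        n_de = int(round(config.frac_de_protein * config.n_proteins))
        de_idx = rng.choice(config.n_proteins, size=n_de, replace=False)
        de = np.zeros(config.n_proteins, dtype=bool)
        de[de_idx] = True
        lo, hi = config.protein_effect_range
        effects = np.zeros(config.n_proteins)
        effects[de] = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    # abundance relative to wild-type; pooled reference = mean across samples
    abund = np.ones((config.n_proteins, len(samples)))
    is_ko = np.array([s.startswith("KO") for s in samples])
    abund[:, is_ko] = 2.0 ** effects[:, None]
    ref = abund.mean(axis=1, keepdims=True)
    log2_ratio = pd.DataFrame(np.log2(abund / ref), index=proteins, columns=samples)

    bias = np.ones((len(replicates), config.n_channels))
    b = np.log(config.max_channel_bias)
    for r in range(len(replicates)):
        bias[r] = np.exp(rng.uniform(-b, b, size=config.n_channels))
        # reference channel of every run in this replicate is pinned to 1.0
        bias[r, _reference_position(r, config)] = 1.0
    channel_bias = pd.DataFrame(bias, index=list(replicates), columns=list(config.channel_labels))
    return SimTruth(
        protein_log2_ratio=log2_ratio,
        protein_de_flags=pd.Series(de, index=proteins, name="de"),
        channel_bias=channel_bias,
    )


def _reference_position(replicate_index: int, config: SimConfig) -> int:
    # channel assignment rotates by one slot between technical replicates
    return replicate_index % config.n_channels


def run_designs(config: SimConfig, replicate_id: str, replicate_index: int):
    """Channel->sample maps for the runs of one technical replicate.

    Samples are split into blocks of (n_channels - 1); within each run the
    internal standard plus the block occupy the channels, rotated by the
    replicate index so channel bias and sample ratios stay identifiable.
    """
    from .itraq import RunDesign  # local import to avoid a cycle

    samples = protein_sample_ids(config)
    per_run = config.n_channels - 1
    designs = []
    shift = replicate_index
    labels = config.channel_labels
    for block_i in range(0, len(samples), per_run):
        block = samples[block_i:block_i + per_run]
        run_id = f"{replicate_id}-run{block_i // per_run + 1}"
        roles = ["__IS__"] + block  # role j sits on channel (j + shift) % n
        chan_of = {j: labels[(j + shift) % config.n_channels] for j in range(len(roles))}
        reference = chan_of[0]
        mapping = {chan_of[j]: roles[j] for j in range(1, len(roles))}
        designs.append(RunDesign(
            run_id=run_id,
            channel_to_sample=mapping,
            reference_channel=reference,
            replicate_id=replicate_id,
        ))
    return designs


def simulate_itraq_run(
    config: SimConfig, truth: SimTruth, replicate_id: str, replicate_index: int = 0
):
    """One technical replicate: peptide-spectrum reporter table + run designs.

    Each peptide's base intensity is lognormal; the reference channel reads
    ``base * mean(sample abundances)`` and each sample channel reads
    ``base * abundance * channel_bias``, all times mean-one lognormal noise,
    so the expected sample/reference ratio is exactly
    ``2**protein_log2_ratio * bias``.  A configured fraction of sample-channel
    observations is inflated by a log-uniform [3, 10] factor to create
    regression outliers.
    """
    if truth.protein_log2_ratio is None or truth.channel_bias is None:
        raise ConfigError("truth lacks protein ratios / channel bias")
    if config.n_proteins == 0 or config.n_channels == 0:
        raise ConfigError("need at least one protein and one channel")
    rng = _rng(config, "itraq", replicate_id)
    designs = run_designs(config, replicate_id, replicate_index)
    bias = truth.channel_bias.loc[replicate_id]
    abund = 2.0 ** truth.protein_log2_ratio  # proteins x samples, rel. to pooled ref
    labels = list(config.channel_labels)
    rows = []
    for design in designs:
        for protein in truth.protein_log2_ratio.index:
            n_pep = config.peptides_min + rng.poisson(
                max(config.peptides_mean - config.peptides_min, 0.0)
            )
            for pep_i in range(n_pep):
                base = float(np.exp(rng.normal(config.intensity_log_mean,
                                               config.intensity_log_sd)))
                n_spec = 1 + int(rng.random() < config.extra_spectrum_prob)
                for spec_i in range(n_spec):
                    intens = {}
                    ref_val = base * 1.0  # pooled reference abundance is 1 by construction
                    intens[design.reference_channel] = ref_val * float(
                        _noise_factor(rng, config.noise_cv)
                    )
                    for channel, sample in design.channel_to_sample.items():
                        y = base * float(abund.at[protein, sample]) * float(bias[channel])
                        y *= float(_noise_factor(rng, config.noise_cv))
                        if rng.random() < config.outlier_fraction:
                            y *= float(np.exp(rng.uniform(np.log(3.0), np.log(10.0))))
                        intens[channel] = y
                    rows.append({
                        "run_id": design.run_id,
                        "protein_id": protein,
                        "peptide_key": f"{protein}_pep{pep_i+1:02d}",
                        **{lab: intens.get(lab, 0.0) for lab in labels},
                    })
    table = pd.DataFrame(rows, columns=["run_id", "protein_id", "peptide_key", *labels])
    return table, designs


def simulate_experiment(config: SimConfig, truth: SimTruth | None = None,
                        replicates: tuple[str, ...] = ("A", "B")):
    """Full two-replicate proteomic experiment: [(table, designs), ...] + truth."""
    if truth is None:
        truth = make_protein_truth(config, replicates)
    out = []
    for i, rep in enumerate(replicates):
        table, designs = simulate_itraq_run(config, truth, rep, replicate_index=i)
        out.append((table, designs))
    return out, truth


def simulate_expression_matrix(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Transcript matrix on the log2 scale with planted effects.

    Per-feature variances are drawn from a scaled inverse-chi-square
    (``sigma_g^2 = d0 * s0^2 / chi2(d0)``) so the empirical-Bayes prior
    estimator can be validated against the generating hyperparameters.
    """
    if config.n_per_group_transcript < 2:
        raise ConfigError("need >=2 samples per group")
    rng = _rng(config, "transcript")
    n = config.n_features_transcript
    features = [f"T{i+1:06d}" for i in range(n)]
    n_de = int(round(config.frac_de * n))
    de = np.zeros(n, dtype=bool)
    de[rng.choice(n, size=n_de, replace=False)] = True
    lo, hi = config.effect_range
    effects = np.zeros(n)
    effects[de] = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    sigma2 = config.var_prior_df * config.var_prior_scale / rng.chisquare(
        config.var_prior_df, size=n
    )
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    k = config.n_per_group_transcript
    samples = [f"KO{i+1:02d}" for i in range(k)] + [f"WT{i+1:02d}" for i in range(k)]
    groups = pd.Series([GROUP_KO] * k + [GROUP_WT] * k, index=samples)
    means = mu[:, None] + effects[:, None] * (groups.to_numpy() == GROUP_KO)[None, :]
    values = means + rng.normal(0.0, 1.0, size=(n, 2 * k)) * np.sqrt(sigma2)[:, None]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), groups)
    truth = SimTruth(
        de_flags=pd.Series(de, index=features, name="de"),
        effect_sizes=pd.Series(effects, index=features, name="log2_effect"),
        feature_sigma2=pd.Series(sigma2, index=features, name="sigma2"),
    )
    return matrix, truth


def simulate_metabolite_table(
    config: SimConfig, planted_log2_effects: dict[str, float] | None = None
) -> tuple[ExpressionMatrix, SimTruth]:
    """Plasma metabolite concentrations (linear positive scale, lognormal noise).

    ``planted_log2_effects`` pins specific compounds to exact effects (e.g. a
    244-fold bile-acid surge) on top of the random differential minority.
    """
    if config.n_per_group_metabolite < 2:
        raise ConfigError("need >=2 samples per group")
    rng = _rng(config, "metabolite")
    n = config.n_features_metabolite
    features = [f"M{i+1:04d}" for i in range(n)]
    n_de = int(round(config.frac_de_metabolite * n))
    de = np.zeros(n, dtype=bool)
    de[rng.choice(n, size=n_de, replace=False)] = True
    lo, hi = config.metabolite_effect_range
    effects = np.zeros(n)
    effects[de] = rng.uniform(lo, hi, size=n_de) * rng.choice([-1.0, 1.0], size=n_de)
    if planted_log2_effects:
        for fid, eff in planted_log2_effects.items():
            i = features.index(fid)
            effects[i] = eff
            de[i] = eff != 0.0
    mu = rng.normal(4.0, 1.5, size=n)  # log2 baseline concentration
    k = config.n_per_group_metabolite
    samples = [f"KO{i+1:02d}" for i in range(k)] + [f"WT{i+1:02d}" for i in range(k)]
    groups = pd.Series([GROUP_KO] * k + [GROUP_WT] * k, index=samples)
    means = mu[:, None] + effects[:, None] * (groups.to_numpy() == GROUP_KO)[None, :]
    log2_vals = means + rng.normal(0.0, config.metabolite_noise_sd, size=(n, 2 * k))
    matrix = ExpressionMatrix(
        pd.DataFrame(2.0 ** log2_vals, index=features, columns=samples), groups, scale="linear"
    )
    truth = SimTruth(
        metabolite_de_flags=pd.Series(de, index=features, name="de"),
        metabolite_effects=pd.Series(effects, index=features, name="log2_effect"),
    )
    return matrix, truth


def simulate_genesets(
    feature_ids,
    de_flags: pd.Series,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 100),
    n_planted: int = 3,
    planted_de_frac: float = 0.5,
    seed: int = 0,
):
    """Random gene sets plus a few planted to be enriched for DE features.

    Planted sets draw ``planted_de_frac`` of their members from the DE pool
    (far above the background DE rate); null sets sample the universe
    uniformly.  Returns ``(sets, planted_ids)`` where ``sets`` maps
    set id -> (name, members).
    """
    rng = np.random.default_rng([seed, zlib.crc32(b"genesets")])
    universe = np.asarray(list(feature_ids))
    de_ids = np.asarray(de_flags.index[de_flags])
    non_de_ids = np.asarray(de_flags.index[~de_flags])
    if n_planted > n_sets:
        raise ConfigError("n_planted cannot exceed n_sets")
    lo, hi = set_size_range
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_ids = []
    for i in range(n_sets):
        set_id = f"GS{i+1:04d}"
        m = int(rng.integers(lo, hi + 1))
        if i < n_planted and de_ids.size > 0:
            k_de = min(int(round(planted_de_frac * m)), de_ids.size)
            members = list(rng.choice(de_ids, size=k_de, replace=False))
            members += list(rng.choice(non_de_ids, size=m - k_de, replace=False))
            name = f"planted enriched set {i+1}"
            planted_ids.append(set_id)
        else:
            members = list(rng.choice(universe, size=min(m, universe.size), replace=False))
            name = f"random set {i+1}"
        sets[set_id] = (name, frozenset(members))
    return sets, planted_ids
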