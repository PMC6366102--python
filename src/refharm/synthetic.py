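"""Synthetic multi-platform expression studies with ground truth.

The generator emulates the structure of the reference-RNA benchmark
designs used to stress cross-platform methods: four sample types where A
and B are two distinct reference transcriptomes and C and D are their
3:1 and 1:3 mixtures, each profiled in replicate on several platforms.
Platform distortion is modeled as gene-specific multiplicative probe
affinity x a power-law compression of the true signal x lognormal noise
for microarray-like platforms, and as negative-binomial counts with a
library-size mean for sequencing-like platforms.  Gene-specific affinity
is the crucial ingredient: it survives quantile normalization (it
reorders genes within a sample) and therefore keeps naive normalizations
platform-clustered, while remaining correctable by a block-model
harmonizer.

A reference world is generated alongside the study: tissue-like centroids
spread along the A-to-B axis (brain and a nerve-like tissue at the B
end, the rest near A, mirroring the composition of the real reference
RNAs), from which a definitive reference dataset Q (tissues x
replicates, its own platform) and an auxiliary calibration dataset P0
(heterogeneous tissue mixtures, yet another platform) are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

__all__ = [
    "PlatformSpec",
    "SyntheticStudyConfig",
    "SyntheticStudy",
    "generate_base_profiles",
    "generate_study",
    "generate_reference_sets",
    "default_study_config",
]

MICROARRAY = "microarray"
SEQUENCING = "sequencing"

DEFAULT_MIX_DESIGN = {
    "A": (1.0, 0.0),
    "B": (0.0, 1.0),
    "C": (0.75, 0.25),
    "D": (0.25, 0.75),
}


@dataclass(frozen=True)
class PlatformSpec:
    """One platform's distortion parameters.

    ``gene_affinity_sd`` is the sd (natural-log units) of the per-gene
    multiplicative probe affinity; ``gamma_range`` bounds the platform's
    signal-compression exponent; ``noise_sd`` (ln units) the replicate
    lognormal noise.  Sequencing platforms draw integer counts from
    NB(mean proportional to ``library_size``, size ``nb_size``) instead.
    """

    name: str
    kind: str = MICROARRAY
    gene_affinity_sd: float = 0.9
    gamma_range: tuple[float, float] = (0.85, 1.15)
    noise_sd: float = 0.15
    nb_size: float = 8.0
    library_size: float = 2e6
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in (MICROARRAY, SEQUENCING):
            raise ValueError(f"unknown platform kind {self.kind!r}")
        if self.gene_affinity_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("platform sds must be > 0")


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Full description of one synthetic multi-platform study."""

    n_genes: int = 2000
    platforms: tuple[PlatformSpec, ...] = ()
    n_replicates_per_type: int = 5
    mix_design: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MIX_DESIGN)
    )
    de_fraction: float = 0.3
    de_log2_sd: float = 2.0
    n_tissues: int = 10
    samples_per_tissue: int = 10
    n_p0_samples: int = 39
    tissue_effect_sd: float = 0.9
    within_tissue_sd: float = 0.15
    p0_mixing_alpha: float = 0.3
    p0_sample_noise_sd: float = 1.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 50:
            raise ValueError("n_genes must be >= 50")
        for t, (wa, wb) in self.mix_design.items():
            if wa < 0 or wb < 0 or abs(wa + wb - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture weights for type {t!r} must be >= 0 and sum to 1"
                )
        if self.tissue_effect_sd <= 0 or self.within_tissue_sd <= 0:
            raise ValueError("sds must be > 0")
        if not self.platforms:
            object.__setattr__(
                self, "platforms", tuple(default_study_config().platforms)
            )


@dataclass
class SyntheticStudy:
    """Per-platform matrices plus the generating truth."""

    matrices: list[ExpressionMatrix]
    truth: dict
    config: SyntheticStudyConfig


def default_study_config(
    include_sequencing: bool = False,
    n_genes: int = 2000,
    n_replicates_per_type: int = 5,
    seed: int = 1,
) -> SyntheticStudyConfig:
    """The default benchmark: 3 microarray platforms, optionally + 1 RNA-seq."""
    # distinct overall intensity scales: platforms report in different
    # units/dynamic ranges, so raw value distributions are far apart
    platforms = [
        PlatformSpec("array1", scale_factor=1.0),
        PlatformSpec("array2", scale_factor=8.0),
        PlatformSpec("array3", scale_factor=0.25),
    ]
    if include_sequencing:
        platforms.append(PlatformSpec("rnaseq", kind=SEQUENCING))
    return SyntheticStudyConfig(
        n_genes=n_genes,
        platforms=tuple(platforms),
        n_replicates_per_type=n_replicates_per_type,
        seed=seed,
    )


def _world(config: SyntheticStudyConfig) -> dict:
    """The shared ground truth: tissue centroids and the two reference RNAs.

    A brain-axis effect vector (a ``de_fraction`` gene subset with
    Normal(0, ``de_log2_sd``) log2 effects) separates brain-like from
    pooled-tissue expression.  Tissue centroids sit along this axis — two
    at the brain end (brain and a nerve-like neighbour), the rest near
    the pool end — each with its own modular identity built from a few
    shared gene factors (transcriptional programs) plus a small
    gene-private term, i.e. the low-rank correlated structure real
    transcriptomes have.  Reference RNA B is the brain centroid;
    reference RNA A is a fixed uneven pool of the non-brain centroids,
    sharing expression direction with the non-brain tissues just as a
    universal reference RNA pooled from non-brain material does.
    """
    if config.n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    rng0 = np.random.default_rng([int(config.seed), 0])
    base = np.exp(rng0.normal(3.0, 1.2, config.n_genes))
    de_mask = rng0.random(config.n_genes) < config.de_fraction
    effects = rng0.normal(0.0, config.de_log2_sd, config.n_genes) * de_mask
    brain_axis = np.log(2.0) * effects  # ln units

    rng = np.random.default_rng([int(config.seed), 1])
    lam = np.concatenate([[1.0, 0.9], rng.uniform(0.0, 0.2, config.n_tissues - 2)])
    n_factors = 3
    factors = rng.normal(0.0, 1.0, (n_factors, config.n_genes))
    loadings = rng.normal(0.0, 1.0, (config.n_tissues, n_factors))
    modular = (config.tissue_effect_sd / np.sqrt(n_factors)) * (loadings @ factors)
    private = rng.normal(0.0, 0.2, (config.n_tissues, config.n_genes))
    centroids = base[None, :] * np.exp(
        lam[:, None] * brain_axis[None, :] + modular + private
    )
    # unequal pooling: geometric contributions over a shuffled tissue order,
    # so the pool always has a dominant component anchoring it (and its
    # mixtures) to a specific non-brain identity
    n_pool = config.n_tissues - 2
    pool_weights = 0.5 ** np.arange(1, n_pool + 1)
    pool_weights /= pool_weights.sum()
    rng.shuffle(pool_weights)
    profile_a = pool_weights @ centroids[2:]
    profile_b = centroids[0]
    return {
        "base": base,
        "de_mask": de_mask,
        "de_effects": effects,
        "centroids": centroids,
        "lam": lam,
        "pool_weights": pool_weights,
        "profile_a": profile_a,
        "profile_b": profile_b,
    }


def generate_base_profiles(
    n_genes: int,
    seed: int,
    de_fraction: float = 0.3,
    de_log2_sd: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two linear-scale ground-truth transcriptomes (A, B).

    B is a brain-like transcriptome: a lognormal abundance vector with a
    ``de_fraction`` subset of genes shifted by Normal(0, ``de_log2_sd``)
    log2 effects along the brain axis.  A is a pooled non-brain reference
    built from the same tissue world, mirroring a universal reference RNA
    pooled from non-brain material.
    """
    cfg = SyntheticStudyConfig(
        n_genes=n_genes, seed=seed, de_fraction=de_fraction, de_log2_sd=de_log2_sd
    )
    world = _world(cfg)
    return world["profile_a"], world["profile_b"]


def _type_signals(config: SyntheticStudyConfig) -> dict[str, np.ndarray]:
    world = _world(config)
    a, b = world["profile_a"], world["profile_b"]
    return {
        t: wa * a + wb * b for t, (wa, wb) in sorted(config.mix_design.items())
    }


def _tissue_centroids(config: SyntheticStudyConfig) -> np.ndarray:
    return _world(config)["centroids"]


def _observe(
    signal: np.ndarray,
    spec: PlatformSpec,
    gains: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One observed sample column under a platform's distortion."""
    if spec.kind == MICROARRAY:
        noise = np.exp(rng.normal(0.0, spec.noise_sd, signal.shape))
        return spec.scale_factor * gains * signal**gamma * noise
    biased = gains * signal**gamma  # gene-specific quantification bias
    mean = spec.library_size * biased / biased.sum()
    p = spec.nb_size / (spec.nb_size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(spec.nb_size, p).astype(float)


def _platform_params(
    spec: PlatformSpec, config: SyntheticStudyConfig, stream: list
) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng([int(config.seed), *stream])
    gains = np.exp(rng.normal(0.0, spec.gene_affinity_sd, config.n_genes))
    gamma = float(rng.uniform(*spec.gamma_range))
    return gains, gamma


def generate_study(config: SyntheticStudyConfig) -> SyntheticStudy:
    """Generate the per-platform observed matrices and their truth.

    Every sample type's true signal is the stated linear mixture of the
    two base transcriptomes; each platform observes every type in
    ``n_replicates_per_type`` independent replicates under its own fixed
    affinity vector and compression exponent.  Bit-reproducible given the
    config.
    """
    signals = _type_signals(config)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    matrices = []
    truth_platforms = {}
    for p_idx, spec in enumerate(config.platforms):
        gains, gamma = _platform_params(spec, config, [2, p_idx, 0])
        rng = np.random.default_rng([int(config.seed), 2, p_idx, 1])
        cols, ids, bio = [], [], []
        for t, s in signals.items():
            for rep in range(config.n_replicates_per_type):
                cols.append(_observe(s, spec, gains, gamma, rng))
                ids.append(f"{spec.name}_{t}{rep + 1}")
                bio.append(t)
        values = pd.DataFrame(np.column_stack(cols), index=genes, columns=ids)
        matrices.append(
            ExpressionMatrix(
                values,
                pd.Series(spec.name, index=ids),
                pd.Series(bio, index=ids),
                scale="linear",
            )
        )
        truth_platforms[spec.name] = {"gains": gains, "gamma": gamma, "kind": spec.kind}
    truth = {
        "signals": signals,
        "genes": genes,
        "platforms": truth_platforms,
        "mix_design": dict(config.mix_design),
    }
    return SyntheticStudy(matrices, truth, config)


def generate_reference_sets(
    config: SyntheticStudyConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Synthetic stand-ins for the calibration (P0) and reference (Q) sets.

    Q: ``n_tissues`` tissue centroids x ``samples_per_tissue`` replicates
    with within-tissue lognormal noise, observed through Q's own platform
    distortion.  P0: ``n_p0_samples`` heterogeneous samples, each a
    Dirichlet mixture of the tissue centroids, observed through a distinct
    platform distortion.  Both share the study's gene space and are
    bit-reproducible given the config.
    """
    centroids = _tissue_centroids(config)
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    q_spec = PlatformSpec("reference_array", gene_affinity_sd=0.6, noise_sd=0.15)
    p0_spec = PlatformSpec("calibration_array", gene_affinity_sd=0.6, noise_sd=0.15)

    q_gains, q_gamma = _platform_params(q_spec, config, [3, 0])
    rng_q = np.random.default_rng([int(config.seed), 3, 1])
    cols, ids, bio = [], [], []
    for k in range(config.n_tissues):
        for rep in range(config.samples_per_tissue):
            s = centroids[k] * np.exp(
                rng_q.normal(0.0, config.within_tissue_sd, config.n_genes)
            )
            cols.append(_observe(s, q_spec, q_gains, q_gamma, rng_q))
            ids.append(f"Q_t{k:02d}_{rep + 1}")
            bio.append(f"tissue{k:02d}")
    Q = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=genes, columns=ids),
        pd.Series(q_spec.name, index=ids),
        pd.Series(bio, index=ids),
        scale="linear",
    )

    p0_gains, p0_gamma = _platform_params(p0_spec, config, [4, 0])
    rng_p = np.random.default_rng([int(config.seed), 4, 1])
    cols, ids = [], []
    for j in range(config.n_p0_samples):
        # sparse mixtures: calibration samples lean toward individual
        # tissues, making P0 span the biological space instead of sitting
        # at its mean
        weights = rng_p.dirichlet(np.full(config.n_tissues, config.p0_mixing_alpha))
        s = weights @ centroids
        # individual biological variability: the calibration set is
        # deliberately more dispersed per gene than the tight reference
        s = s * np.exp(rng_p.normal(0.0, config.p0_sample_noise_sd, config.n_genes))
        cols.append(_observe(s, p0_spec, p0_gains, p0_gamma, rng_p))
        ids.append(f"P0_{j + 1:02d}")
    P0 = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=genes, columns=ids),
        pd.Series(p0_spec.name, index=ids),
        pd.Series("mixed", index=ids),
        scale="linear",
    )
    return P0, Q
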