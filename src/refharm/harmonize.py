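"""Per-profile harmonization driver.

Each expression profile is harmonized independently of every other input
profile: it is column-bound to a fixed auxiliary calibration dataset P0,
jointly quantile-normalized with it, log2-transformed, pushed through the
block-model transform into the frame of the fixed reference dataset Q, and
the single transformed column is extracted.  Because the only companions a
profile ever sees are P0 and Q, arbitrarily many platforms can be
harmonized one profile at a time into one comparable output space.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import LOG2, ExpressionMatrix, concat_samples, intersect_genes
from .normalize import quantile_normalize
from .xpn import HarmonizationConfig, transform_to_reference

__all__ = ["HarmonizerBundle", "build_bundle", "harmonize_profile", "harmonize_study"]


@dataclass
class HarmonizerBundle:
    """Frozen companions of every harmonization: P0, Q, config, gene space.

    ``P0`` is the auxiliary calibration dataset each profile is
    quantile-normalized with; ``Q`` is the reference definitive dataset
    whose distributional frame all outputs share.  Both are restricted to
    ``gene_space`` (their gene intersection, lexicographic order).
    """

    P0: ExpressionMatrix
    Q: ExpressionMatrix
    config: HarmonizationConfig = field(default_factory=HarmonizationConfig)
    gene_space: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.P0.n_samples < 2:
            raise ValueError("calibration dataset P0 needs >= 2 samples")
        if self.Q.n_samples < self.config.L:
            raise ValueError(
                f"reference Q needs >= L={self.config.L} samples, has {self.Q.n_samples}"
            )
        # cached log2 view of Q used by every profile
        self._Q_log = self.Q.subset_genes(self.gene_space).to_log2()
        self._P0_linear = self.P0.subset_genes(self.gene_space).to_linear()


def build_bundle(
    P0: ExpressionMatrix,
    Q: ExpressionMatrix,
    config: HarmonizationConfig | None = None,
) -> HarmonizerBundle:
    """Restrict P0 and Q to their common gene space and freeze them."""
    P0r, Qr = intersect_genes([P0, Q])
    return HarmonizerBundle(P0r, Qr, config or HarmonizationConfig(), P0r.gene_ids)


def _profile_seed(base_seed: int, sample_id: str) -> int:
    """Deterministic per-profile seed, independent of processing order."""
    return (int(base_seed) ^ zlib.crc32(str(sample_id).encode())) & 0x7FFFFFFF


def _restrict_profile(
    profile: ExpressionMatrix, gene_space: list[str], min_overlap: float
) -> tuple[ExpressionMatrix, list[str]]:
    """Reorder a profile onto the bundle gene space, imputing rare gaps.

    Genes of the working space missing from the profile (tolerated up to
    ``1 - min_overlap`` of the space) are imputed at the profile's minimum
    observed value, i.e. treated as at the detection floor; the imputed
    list is recorded for auditability.
    """
    have = set(profile.gene_ids)
    present = [g for g in gene_space if g in have]
    overlap = len(present) / len(gene_space)
    if overlap < min_overlap:
        raise ValueError(
            f"profile covers only {overlap:.1%} of the working gene space "
            f"(minimum {min_overlap:.0%})"
        )
    linear = profile.to_linear()
    col = linear.values.reindex(gene_space)
    missing = [g for g in gene_space if g not in have]
    if missing:
        col.loc[missing] = float(np.nanmin(linear.values.to_numpy()))
    out = ExpressionMatrix(
        col, linear.platform, linear.bio_label, scale="linear", attrs=dict(linear.attrs)
    )
    return out, missing


def harmonize_profile(
    profile: ExpressionMatrix, bundle: HarmonizerBundle
) -> ExpressionMatrix:
    """Harmonize one single-sample profile into the reference frame.

    Steps: restrict to the bundle gene space; column-bind to P0; joint
    quantile normalization of the merged (|P0|+1)-column matrix;
    log2(x+1); block-model transform into Q's frame; return the single
    transformed column (log2 units).  Deterministic given the bundle
    config seed and the sample id.
    """
    if profile.n_samples != 1:
        raise ValueError("harmonize_profile expects a single-sample matrix")
    sample_id = profile.sample_ids[0]
    restricted, missing = _restrict_profile(
        profile, bundle.gene_space, bundle.config.min_gene_overlap
    )
    merged = concat_samples([bundle._P0_linear, restricted])
    merged = quantile_normalize(merged).to_log2()
    cfg = bundle.config.with_seed(_profile_seed(bundle.config.seed, sample_id))
    transformed = transform_to_reference(merged, bundle._Q_log, cfg)
    out = transformed.subset_samples([sample_id])
    out.scale = LOG2
    if missing:
        out.attrs["imputed_genes"] = missing
    return out


def harmonize_study(
    matrices: list[ExpressionMatrix], bundle: HarmonizerBundle
) -> ExpressionMatrix:
    """Harmonize every sample of every input matrix, one profile at a time.

    The output is one combined matrix over the bundle gene space carrying
    each sample's platform and biological labels.  Because profiles are
    processed independently with per-sample seeds, the result does not
    depend on how samples are grouped into input matrices or on their
    order.
    """
    seen: set[str] = set()
    for m in matrices:
        for s in m.sample_ids:
            if s in seen:
                raise ValueError(f"duplicate sample id across inputs: {s!r}")
            seen.add(s)
    columns: list[ExpressionMatrix] = []
    for m in matrices:
        for s in m.sample_ids:
            columns.append(harmonize_profile(m.subset_samples([s]), bundle))
    order = np.argsort([c.sample_ids[0] for c in columns], kind="mergesort")
    columns = [columns[i] for i in order]
    values = pd.concat([c.values for c in columns], axis=1)
    platform = pd.concat([c.platform for c in columns])
    bio = pd.concat([c.bio_label for c in columns])
    out = ExpressionMatrix(values, platform, bio, scale=LOG2)
    imputed = {
        c.sample_ids[0]: c.attrs["imputed_genes"]
        for c in columns
        if "imputed_genes" in c.attrs
    }
    if imputed:
        out.attrs["imputed_genes"] = imputed
    return out
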