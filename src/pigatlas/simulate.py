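"""Synthetic expression atlases with planted coexpression structure.

The generator emulates the structure of a multi-tissue expression atlas so
that every downstream stage (QC, network construction, Markov clustering,
profiling, the signature statistic) can be validated against known ground
truth:

* **tissue-specific clusters** — genes sharing a profile that is high
  (``baseline * fold_change``) in a target tissue subset and baseline
  elsewhere;
* **housekeeping clusters** — genes near-constant across all tissues;
* **pathway clusters** — genes sharing a profile that varies across all
  tissues at a range of levels (e.g. oxidative-phosphorylation-like);
* **unique-profile genes** — a minority of genes correlated with nothing.

Every gene gets its own scale factor drawn log-uniformly over one decade,
so a planted cluster contains members at different absolute intensities
(correlation, not level, is what groups them).  Noise is multiplicative
log-normal: additive Gaussian with standard deviation ``noise_sd_log2`` on
the log2 scale, the natural noise model for normalized intensity data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, SampleMetadata


@dataclass(frozen=True)
class PlantedCluster:
    """One planted coexpression cluster.

    ``kind`` is ``tissue_specific`` (high in ``target_tissues`` by
    ``fold_change``, baseline elsewhere), ``housekeeping`` (near-uniform)
    or ``pathway`` (a shared random profile across tissues).
    """

    size: int
    kind: str = "tissue_specific"
    target_tissues: tuple[int, ...] = (0,)
    fold_change: float = 16.0

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if self.kind not in ("tissue_specific", "housekeeping", "pathway"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.kind == "tissue_specific" and self.fold_change <= 1:
            raise ValueError("fold_change must be > 1 for tissue_specific clusters")


def _default_clusters() -> tuple[PlantedCluster, ...]:
    # Five tissue-specific clusters (one per tissue), one housekeeping,
    # one pathway cluster — the planted structure the atlas emulates.
    return tuple(
        [PlantedCluster(50, "tissue_specific", (t,), 16.0) for t in range(5)]
        + [PlantedCluster(30, "housekeeping"), PlantedCluster(30, "pathway")]
    )


@dataclass(frozen=True)
class AtlasSimConfig:
    """Study conditions for the synthetic atlas.

    Defaults: 8 tissues x 2 replicates, five 50-gene tissue-specific
    clusters at 16-fold induction over a baseline of 20, plus housekeeping
    and pathway clusters, 100 unique-profile genes, and log2-scale noise of
    0.25.  The baseline of 20 and fold of 16 put planted genes on both
    sides of an absolute-intensity filter at 50, so low-intensity filtering
    is exercised meaningfully.
    """

    n_tissues: int = 8
    replicates_per_tissue: int = 2
    planted_clusters: tuple[PlantedCluster, ...] = field(
        default_factory=_default_clusters
    )
    baseline_intensity: float = 20.0
    noise_sd_log2: float = 0.25
    n_unique_genes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 1 or self.replicates_per_tissue < 1:
            raise ValueError("need at least one tissue and one replicate")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        for c in self.planted_clusters:
            for t in c.target_tissues:
                if c.kind == "tissue_specific" and not (0 <= t < self.n_tissues):
                    raise ValueError(f"target tissue {t} out of range")


def _draw_unique_profile(
    rng: np.random.Generator,
    n_tissues: int,
    anchors: list[np.ndarray],
    max_abs_r: float = 0.6,
    max_tries: int = 1000,
) -> np.ndarray:
    """Random linear-scale tissue profile with |Pearson r| < ``max_abs_r``
    against every anchor profile.

    Profiles are 2**(1.5 * N(0,1)) per tissue; the correlation screen runs
    on the *linear* scale, the scale on which downstream edges are defined
    (exponentiation concentrates variance in the top tissue, so log-scale
    decorrelation alone would not be enough).  Rejection sampling,
    deterministic given the generator state; if no candidate passes within
    ``max_tries`` the least-correlated one is used.
    """
    best, best_worst = None, np.inf
    for _ in range(max_tries):
        cand = np.power(2.0, 1.5 * rng.normal(0.0, 1.0, size=n_tissues))
        if n_tissues < 3 or not anchors:
            return cand
        if np.std(cand) == 0:
            continue
        worst = max(abs(np.corrcoef(cand, a)[0, 1]) for a in anchors)
        if worst < max_abs_r:
            return cand
        if worst < best_worst:
            best, best_worst = cand, worst
    return best if best is not None else cand


@dataclass
class GroundTruth:
    """Gene -> planted cluster label; ``unique`` for unplanted genes."""

    mapping: dict[str, str]

    def labels_for(self, genes: list[str]) -> list[str]:
        return [self.mapping[g] for g in genes]


def generate_atlas(
    config: AtlasSimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, GroundTruth]:
    """Generate an atlas matrix, its sample metadata and the ground truth.

    Deterministic for a fixed ``config.seed`` (bit-for-bit).
    """
    rng = np.random.default_rng(config.seed)
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    samples, rows_meta = [], []
    for t in tissues:
        for r in range(1, config.replicates_per_tissue + 1):
            sid = f"{t}_r{r}"
            samples.append(sid)
            rows_meta.append((sid, t, r, t))
    meta = SampleMetadata(
        pd.DataFrame(rows_meta, columns=["sample_id", "tissue", "replicate", "class"])
    )
    tissue_of_sample = np.repeat(
        np.arange(config.n_tissues), config.replicates_per_tissue
    )

    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    profiles: list[np.ndarray] = []  # per-gene per-tissue mean (linear scale)
    _base_profiles: list[np.ndarray] = []  # one per planted cluster

    for ci, cl in enumerate(config.planted_clusters, start=1):
        label = f"cluster{ci:02d}"
        base = np.full(config.n_tissues, config.baseline_intensity)
        if cl.kind == "tissue_specific":
            base = base.copy()
            base[list(cl.target_tissues)] *= cl.fold_change
        elif cl.kind == "pathway":
            # shared profile varying over all tissues at a range of levels
            base = config.baseline_intensity * np.power(
                2.0, rng.uniform(-2.0, 2.0, size=config.n_tissues)
            )
        # housekeeping: flat baseline
        _base_profiles.append(base)
        for g in range(cl.size):
            gid = f"{label}_g{g + 1:03d}"
            scale = 10.0 ** rng.uniform(0.0, 1.0)  # one decade of levels
            gene_ids.append(gid)
            truth[gid] = label
            profiles.append(scale * base)

    # Unique-profile genes are *defined* as correlating with nothing: their
    # tissue profiles are redrawn until below |r| 0.6 against every planted
    # base profile (comfortably under any edge threshold used downstream).
    # Chance pairings *among* unique genes are left to the
    # min-component-size filter, as in real data.
    anchors = [p for p in _base_profiles if np.std(p) > 0]
    for g in range(config.n_unique_genes):
        gid = f"unique_g{g + 1:03d}"
        prof = config.baseline_intensity * _draw_unique_profile(
            rng, config.n_tissues, anchors, max_abs_r=0.6
        )
        scale = 10.0 ** rng.uniform(0.0, 1.0)
        gene_ids.append(gid)
        truth[gid] = "unique"
        profiles.append(scale * prof)

    mean = np.stack(profiles)[:, tissue_of_sample]  # genes x samples
    noise = rng.normal(0.0, config.noise_sd_log2, size=mean.shape)
    values = mean * np.power(2.0, noise)
    matrix = ExpressionMatrix(gene_ids, samples, values)
    return matrix, meta, GroundTruth(truth)


def generate_signature_mixture(
    fraction: float,
    n_signature_genes: int = 50,
    seed: int = 0,
    noise_sd_log2: float = 0.0,
    n_source_samples: int = 4,
    n_target_samples: int = 8,
    n_background_genes: int = 50,
    signature_level: float = 500.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """Fixture for the cell-contribution statistic.

    "Pure" source samples express each signature gene at a per-gene level
    L; "mixture" target samples express it at ``fraction * L`` — as if the
    source cell type contributed that fraction of the target tissue's mRNA.
    Background genes are expressed equally everywhere.  With zero noise the
    per-gene max-expression ratio source/target is exactly ``1/fraction``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    sig_genes = [f"sig_g{i + 1:03d}" for i in range(n_signature_genes)]
    bg_genes = [f"bg_g{i + 1:03d}" for i in range(n_background_genes)]
    samples = [f"source_{i + 1}" for i in range(n_source_samples)] + [
        f"target_{i + 1}" for i in range(n_target_samples)
    ]
    levels = signature_level * 10.0 ** rng.uniform(0.0, 1.0, size=n_signature_genes)
    sig = np.empty((n_signature_genes, len(samples)))
    sig[:, :n_source_samples] = levels[:, None]
    sig[:, n_source_samples:] = fraction * levels[:, None]
    bg = np.full((n_background_genes, len(samples)), 100.0)
    values = np.vstack([sig, bg])
    if noise_sd_log2 > 0:
        values = values * np.power(
            2.0, rng.normal(0.0, noise_sd_log2, size=values.shape)
        )
    matrix = ExpressionMatrix(sig_genes + bg_genes, samples, values)
    return matrix, sig_genes
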