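"""Synthetic coupled microbiome-metabolome data with planted biclusters.

The generator emulates the study layout the pipeline targets: a 2x2 diet
design (high/low fat x prebiotic supplement, 10 rats per group), 226
genera of which ~66 are abundant enough to survive the default prevalence
filter, 38 metabolites, and 5 latent blocks that couple subsets of genera
and metabolites through shared per-sample latent factors.  Counts are
drawn multinomially from softmax log-intensities so the planted structure
survives the compositional (relative abundance + clr) steps of the real
pipeline; selected blocks carry diet and supplement effects on their
latent factor, and biomarkers are noisy linear readouts of block latents.
Ground truth (block memberships, latent factors) is returned for recovery
benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .tables import (
    BiomarkerTable,
    CountTable,
    MetaboliteTable,
    SampleDesign,
    ValidationError,
)

__all__ = ["SimConfig", "SimTruth", "generate", "adjusted_rand_index"]

BACKGROUND = -1  # truth label for features outside every planted block

# study-layout defaults: metabolite blocks 11+4+6+10+7 = 38; genus blocks
# 14+10+16+14+12 = 66 (the 60 annotated members per block plus the 6
# unannotated retained genera distributed across blocks -- every retained
# genus belongs to exactly one bicluster)
_DEFAULT_MET_BLOCKS = (11, 4, 6, 10, 7)
_DEFAULT_GEN_BLOCKS = (14, 10, 16, 14, 12)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale simulation parameters.

    Group effects shift a block's latent factor mean by ``delta_fat`` on
    the high-fat diet and ``delta_xos`` under supplementation; defaults
    plant a fat-suppressed block (0), a supplement-suppressed block (3)
    and a block responding to both (4), echoing the qualitative pattern
    the pipeline is meant to detect.
    """

    n_per_group: int = 10
    n_genera: int = 226
    n_metabolites: int = 38
    k_blocks: int = 5
    genus_block_sizes: tuple[int, ...] = _DEFAULT_GEN_BLOCKS
    metabolite_block_sizes: tuple[int, ...] = _DEFAULT_MET_BLOCKS
    n_abundant_background: int = 0
    lam: float = 1.0
    sigma: float = 0.10
    group_effects: dict = field(
        default_factory=lambda: {0: (-1.5, 0.0), 3: (0.0, -1.0), 4: (1.0, -0.5)}
    )
    library_size_mean: float = 5e4
    library_size_sdlog: float = 0.3
    rare_baseline_offset: float = -8.0
    n_biomarkers: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        if self.sigma < 0 or self.lam < 0:
            raise ValidationError("sigma and lam must be nonnegative")
        if len(self.genus_block_sizes) != self.k_blocks or len(
            self.metabolite_block_sizes
        ) != self.k_blocks:
            raise ValidationError("one block size per block is required on each axis")
        if sum(self.genus_block_sizes) + self.n_abundant_background > self.n_genera:
            raise ValidationError("genus block sizes exceed the number of genera")
        if sum(self.metabolite_block_sizes) > self.n_metabolites:
            raise ValidationError("metabolite block sizes exceed the number of metabolites")
        for b in self.group_effects:
            if not (0 <= b < self.k_blocks):
                raise ValidationError(f"group effect refers to unknown block {b}")


@dataclass
class SimTruth:
    """Planted ground truth: block labels, latent factors, effect map."""

    genus_labels: pd.Series
    metabolite_labels: pd.Series
    z: pd.DataFrame  # samples x k latent factors
    group_effects: dict
    seed: int

    def labels_for(self, feature_ids, axis: str) -> np.ndarray:
        source = self.genus_labels if axis == "genera" else self.metabolite_labels
        return source.reindex(list(feature_ids), fill_value=BACKGROUND).to_numpy()


def _design(config: SimConfig) -> SampleDesign:
    rows = []
    for fat in ("HFD", "LFD"):
        for xos in ("no", "yes"):
            for i in range(config.n_per_group):
                label = fat + ("+XOS" if xos == "yes" else "")
                rows.append((f"{label}_{i + 1:02d}", fat, xos))
    frame = pd.DataFrame(rows, columns=["sample_id", "fat", "xos"]).set_index("sample_id")
    return SampleDesign(frame)


def generate(config: SimConfig | None = None):
    """Draw one synthetic dataset.

    Returns ``(counts, metabolites, design, biomarkers, truth)``; fully
    reproducible from ``config.seed``.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    design = _design(config)
    n = len(design.sample_ids)
    k = config.k_blocks

    fat = (design.frame["fat"] == "HFD").to_numpy(dtype=float)
    xos = (design.frame["xos"] == "yes").to_numpy(dtype=float)
    mu = np.zeros((n, k))
    for b, (d_f, d_x) in config.group_effects.items():
        mu[:, b] = d_f * fat + d_x * xos
    z = mu + rng.standard_normal((n, k))

    # genus memberships: planted blocks, then abundant and rare background
    genus_labels = np.full(config.n_genera, BACKGROUND, dtype=int)
    pos = 0
    for b, size in enumerate(config.genus_block_sizes):
        genus_labels[pos : pos + size] = b
        pos += size
    n_abundant = pos + config.n_abundant_background
    genus_ids = [f"genus_{g + 1:03d}" for g in range(config.n_genera)]

    met_labels = np.full(config.n_metabolites, BACKGROUND, dtype=int)
    pos = 0
    for b, size in enumerate(config.metabolite_block_sizes):
        met_labels[pos : pos + size] = b
        pos += size
    met_ids = [f"metabolite_{m + 1:02d}" for m in range(config.n_metabolites)]

    # genus counts: softmax of log-intensities, multinomial at drawn depth
    baseline_g = rng.normal(0.0, 1.0, size=config.n_genera)
    baseline_g[n_abundant:] += config.rare_baseline_offset
    log_intensity = np.tile(baseline_g, (n, 1))
    for g in range(config.n_genera):
        if genus_labels[g] != BACKGROUND:
            log_intensity[:, g] += config.lam * z[:, genus_labels[g]]
    log_intensity += rng.normal(0.0, config.sigma, size=log_intensity.shape)
    probs = np.exp(log_intensity - log_intensity.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    meanlog = np.log(config.library_size_mean) - config.library_size_sdlog**2 / 2.0
    depths = np.maximum(
        rng.lognormal(meanlog, config.library_size_sdlog, size=n).astype(int), 1000
    )
    counts = np.vstack([rng.multinomial(depths[s], probs[s]) for s in range(n)])
    count_table = CountTable(
        pd.DataFrame(counts, index=design.sample_ids, columns=genus_ids),
        taxonomy=_taxonomy(genus_ids, n_abundant, rng),
    )

    # metabolites: log-normal intensities sharing the block latents
    baseline_m = rng.normal(2.0, 1.0, size=config.n_metabolites)
    log_met = np.tile(baseline_m, (n, 1))
    for m in range(config.n_metabolites):
        if met_labels[m] != BACKGROUND:
            log_met[:, m] += config.lam * z[:, met_labels[m]]
    log_met += rng.normal(0.0, config.sigma, size=log_met.shape)
    metabolite_table = MetaboliteTable(
        pd.DataFrame(np.exp(log_met), index=design.sample_ids, columns=met_ids)
    )

    biomarker_table = _biomarkers(config, design, z, fat, rng)

    truth = SimTruth(
        genus_labels=pd.Series(genus_labels, index=genus_ids),
        metabolite_labels=pd.Series(met_labels, index=met_ids),
        z=pd.DataFrame(z, index=design.sample_ids, columns=[f"block_{b}" for b in range(k)]),
        group_effects=dict(config.group_effects),
        seed=config.seed,
    )
    return count_table, metabolite_table, design, biomarker_table, truth


def _taxonomy(genus_ids, n_abundant, rng) -> dict[str, str]:
    """Assign phyla: abundant genera mostly Firmicutes/Bacteroidetes,
    rare background skewed toward minor phyla (so filtering shifts the
    phylum balance, as real prevalence filters do)."""
    phyla_abundant = ["Firmicutes", "Bacteroidetes", "Proteobacteria"]
    phyla_rare = ["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria", "Tenericutes"]
    tax = {}
    for i, g in enumerate(genus_ids):
        if i < n_abundant:
            tax[g] = phyla_abundant[int(rng.choice(3, p=[0.6, 0.3, 0.1]))]
        else:
            tax[g] = phyla_rare[int(rng.choice(5, p=[0.2, 0.3, 0.2, 0.2, 0.1]))]
    return tax


_BIOMARKER_DEFS = [
    # name, block read out, weight on the latent, direct fat-effect weight
    ("triglycerides-liver", 4, 1.0, 1.0),
    ("CLS", 4, 0.8, 0.8),
    ("miR-192-5p", 3, -1.0, 0.0),
    ("miR-21-5p", 0, 1.0, -0.5),
    ("p-AKT-epi", 1, 1.0, 0.0),
    ("AST-gastro", 2, 0.7, 0.0),
]


def _biomarkers(config, design, z, fat, rng) -> BiomarkerTable:
    n = len(design.sample_ids)
    defs = _BIOMARKER_DEFS[: config.n_biomarkers]
    data = {}
    for name, block, w, w_fat in defs:
        block = block % config.k_blocks
        data[name] = w * z[:, block] + w_fat * fat + rng.normal(0.0, 0.5, size=n)
    return BiomarkerTable(pd.DataFrame(data, index=design.sample_ids))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (1 identical, ~0 random)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValidationError("label vectors must have equal length")
    return float(adjusted_rand_score(labels_a, labels_b))
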