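"""Synthetic two-class radiogenomic cohorts with known ground truth.

Real study cohorts of this kind (private MR scans plus matched FFPE RNA-seq)
cannot be redistributed, so every downstream stage is exercised on generated
data instead: tumor volumes whose *texture* — not size — separates the
classes, negative-binomial RNA-seq counts with planted direction-consistent
differentially expressed genes, and gene-set collections containing sets
enriched in each direction.

Design notes
------------
* Texture signal: voxel intensities inside the mask are a Gaussian random
  field (smoothed white noise).  The extra-vesical class uses a larger
  smoothing radius and marginal standard deviation, both scaled by
  ``texture_effect``; at ``texture_effect = 0`` the two class-conditional
  generators are identical.  Mask size distributions are class-independent
  by construction, so volume carries no signal.
* Counts: K_gj ~ NB(mean = s_j * q_g * 2**(beta_g * x_j), dispersion
  alpha_g), with x_j = 1 for extra-vesical samples and library-size factors
  s_j log-uniform in [0.5, 2] so normalization is actually exercised.
* Seeding: one global seed streams to per-case and per-stage sub-seeds via
  ``numpy.random.SeedSequence([seed, stream])``, so adding a case never
  reshuffles the draws of the others and regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import ImageVolume, TumorMask

# The canonical stage-associated genes planted in every non-null cohort:
# higher in low-stage (intra-vesical) cases ...
GENES_UP_IN_LOW = ("HOXB5", "DHRS3", "FABP4")
# ... and higher in high-stage (extra-vesical) cases.
GENES_UP_IN_HIGH = (
    "TAGLN2",
    "HIST1H1D",
    "HIST1H2BD",
    "H2AFX",
    "CLDN3",
    "PLAUR",
)
CANONICAL_GENES = GENES_UP_IN_LOW + GENES_UP_IN_HIGH

_COUNTS_STREAM = 1_000_000
_SETS_STREAM = 2_000_000
_BASELINE_STREAM = 3_000_000


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for a synthetic radiogenomic cohort.

    Defaults mirror a 28-case training cohort (18 intra- / 10 extra-vesical)
    with ~2000 genes, 50 planted DEGs at |log2 fold change| 2, moderate NB
    dispersion, and a 75-set signature collection.
    """

    n_intra: int = 18
    n_extra: int = 10
    volume_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    texture_effect: float = 1.0
    n_genes: int = 2000
    n_de_genes: int = 50
    log2fc: float = 2.0
    nb_dispersion: float = 0.1
    n_gene_sets: int = 75
    set_size: int = 30
    heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_intra < 2 or self.n_extra < 2:
            raise ConfigurationError("need >= 2 cases per class")
        if not (0 <= self.n_de_genes <= self.n_genes):
            raise ConfigurationError("n_de_genes must lie in [0, n_genes]")
        if 0 < self.n_de_genes < len(CANONICAL_GENES):
            raise ConfigurationError(
                f"n_de_genes must be 0 or >= {len(CANONICAL_GENES)} so the "
                "canonical stage genes fit in the planted set"
            )
        if any(v <= 0 for v in self.volume_shape) or any(
            v <= 0 for v in self.voxel_spacing
        ):
            raise ConfigurationError("volume_shape and voxel_spacing must be positive")
        if self.set_size > self.n_genes:
            raise ConfigurationError("set_size must be <= n_genes")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.texture_effect < 0:
            raise ConfigurationError("texture_effect must be >= 0")
        if not 0 <= self.heterogeneity < 1:
            raise ConfigurationError("heterogeneity must lie in [0, 1)")

    @property
    def n_cases(self) -> int:
        return self.n_intra + self.n_extra


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus its planted ground truth."""

    config: CohortConfig
    case_ids: list[str]
    labels: pd.Series  # "intra" / "extra", indexed by case id
    volumes: list[ImageVolume]
    masks: list[TumorMask]
    counts: pd.DataFrame  # genes x samples
    truth: dict = field(default_factory=dict)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


class DegenerateMaskError(RuntimeError):
    """Tumor generation produced an unusable ROI even after retrying."""


def phenotype_scales(config: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-case (texture, expression) effect multipliers.

    With ``heterogeneity = 0`` every extra-vesical case carries both effects
    at full strength.  With ``heterogeneity = h > 0``, extra-vesical cases
    alternate between a texture-dominant phenotype (expression effect scaled
    by 1 - h) and an expression-dominant one (texture effect scaled by
    1 - h) — tumor subpopulations visible to one modality but muted in the
    other, the regime where integrating both modalities genuinely pays.
    Intra-vesical cases always scale 0.
    """
    tex = np.zeros(config.n_cases)
    gen = np.zeros(config.n_cases)
    weak = 1.0 - config.heterogeneity
    for k in range(config.n_extra):
        j = config.n_intra + k
        if k % 2 == 0:
            tex[j], gen[j] = 1.0, weak
        else:
            tex[j], gen[j] = weak, 1.0
    return tex, gen


def generate_tumor_volume(
    class_label: str, config: CohortConfig, case_seed: int, effect_scale: float = 1.0
) -> tuple[ImageVolume, TumorMask]:
    """One tumor volume/mask pair.

    The mask is a single connected ellipsoid-like blob (boundary perturbed by
    smoothed noise, >= 100 voxels) whose expected size does not depend on the
    class; the in-mask intensity field's correlation length and marginal SD
    scale with ``texture_effect`` for extra-vesical cases only.
    """
    if any(v < 16 for v in config.volume_shape):
        raise ConfigurationError("volume_shape must be >= 16 voxels per axis")
    is_extra = class_label == "extra"
    for attempt in range(3):
        rng = _rng(config.seed, case_seed + attempt * 7_777_777)
        shape = tuple(config.volume_shape)
        center = [
            s / 2.0 + rng.uniform(-1.5, 1.5) for s in shape
        ]
        # class-independent radii: size carries no stage signal
        radii = rng.uniform(0.22, 0.32, size=3) * np.asarray(shape)
        grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
        bumps = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        bumps = bumps / (np.std(bumps) + 1e-12)
        mask = (q + 0.15 * bumps) <= 1.0
        labeled, n_comp = ndimage.label(mask)
        if n_comp >= 1:
            sizes = np.bincount(labeled.ravel())[1:]
            mask = labeled == (int(np.argmax(sizes)) + 1)
        # stationary correlated field; class difference only through sigma/sd
        eff = config.texture_effect * effect_scale if is_extra else 0.0
        sigma = 0.8 * (1.0 + eff)
        sd = 0.12 * (1.0 + 0.5 * eff)
        fld = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        fld = (fld - fld.mean()) / (fld.std() + 1e-12)
        intensities = np.clip(
            0.15 + 0.02 * rng.standard_normal(shape), 0.0, None
        )  # background
        intensities[mask] = 0.55 + sd * fld[mask]
        if mask.sum() >= 100 and len(np.unique(intensities[mask])) >= 2:
            cid = f"case_{case_seed:03d}"
            return (
                ImageVolume(intensities, spacing=config.voxel_spacing, case_id=cid),
                TumorMask(mask, case_id=cid),
            )
    raise DegenerateMaskError(
        f"could not generate a usable mask for case seed {case_seed}"
    )


def generate_counts(
    config: CohortConfig,
    labels: pd.Series,
    effect_scales: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """NB count matrix (genes x samples) plus the planted-DEG truth map.

    ``effect_scales`` optionally attenuates the planted fold change per
    sample (see :func:`phenotype_scales`); by default extra-vesical samples
    carry the full effect.
    """
    if len(labels) != config.n_cases:
        raise ConfigurationError("labels length must equal n_intra + n_extra")
    rng = _rng(config.seed, _COUNTS_STREAM)
    genes = list(CANONICAL_GENES) + [
        f"GENE{i:05d}" for i in range(config.n_genes - len(CANONICAL_GENES))
    ]
    planted: dict[str, str] = {}
    beta = np.zeros(config.n_genes)
    if config.n_de_genes > 0 and config.log2fc != 0:
        for i, g in enumerate(GENES_UP_IN_LOW):
            beta[genes.index(g)] = -config.log2fc
            planted[g] = "up_in_low"
        for g in GENES_UP_IN_HIGH:
            beta[genes.index(g)] = config.log2fc
            planted[g] = "up_in_high"
        extra = config.n_de_genes - len(CANONICAL_GENES)
        # which genes are stage-associated is disease biology shared by every
        # cohort (so external validation cohorts carry the same signal), not
        # a per-cohort draw
        rng_disease = np.random.default_rng(
            np.random.SeedSequence(
                [_BASELINE_STREAM + 1, config.n_genes, config.n_de_genes]
            )
        )
        candidates = rng_disease.choice(
            np.arange(len(CANONICAL_GENES), config.n_genes), size=extra, replace=False
        )
        for k, gi in enumerate(sorted(candidates)):
            sign = 1 if k % 2 == 0 else -1
            beta[gi] = sign * config.log2fc
            planted[genes[gi]] = "up_in_high" if sign > 0 else "up_in_low"

    # baseline expression is a property of the gene, not of the cohort:
    # a fixed stream keeps q_g identical across cohorts so that rank-based
    # scores transfer between training and external-validation data, as
    # they do for real transcriptomes
    rng_q = np.random.default_rng(np.random.SeedSequence([_BASELINE_STREAM]))
    q = np.exp(rng_q.uniform(np.log(20.0), np.log(2000.0), size=config.n_genes))
    s = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=config.n_cases))
    x = (labels.to_numpy() == "extra").astype(float)
    if effect_scales is not None:
        x = x * np.asarray(effect_scales, dtype=float)
    mu = s[None, :] * q[:, None] * np.power(2.0, beta[:, None] * x[None, :])

    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    frame = pd.DataFrame(counts, index=genes, columns=list(labels.index))
    truth = {
        "planted_degs": planted,
        "size_factors": {c: float(v) for c, v in zip(labels.index, s)},
    }
    return frame, truth


def generate_gene_sets(truth: dict, config: CohortConfig) -> dict[str, list[str]]:
    """Signature collection: one set enriched per planted direction (when
    DEGs are planted) plus random filler sets, ``n_gene_sets`` in total."""
    rng = _rng(config.seed, _SETS_STREAM)
    genes = list(CANONICAL_GENES) + [
        f"GENE{i:05d}" for i in range(config.n_genes - len(CANONICAL_GENES))
    ]
    planted: dict[str, str] = truth.get("planted_degs", {})
    up_high = [g for g, d in planted.items() if d == "up_in_high"]
    up_low = [g for g, d in planted.items() if d == "up_in_low"]
    null_pool = [g for g in genes if g not in planted]

    sets: dict[str, list[str]] = {}

    def pad(members: list[str]) -> list[str]:
        members = members[: config.set_size]
        need = config.set_size - len(members)
        if need > 0:
            filler = rng.choice(null_pool, size=need, replace=False)
            members = members + [str(g) for g in filler]
        return members

    n_random = config.n_gene_sets
    if up_high:
        sets["SIG_UP_IN_HIGH"] = pad(sorted(up_high))
        n_random -= 1
    if up_low:
        sets["SIG_UP_IN_LOW"] = pad(sorted(up_low))
        n_random -= 1
    for i in range(max(0, n_random)):
        members = rng.choice(null_pool, size=config.set_size, replace=False)
        sets[f"SIG_RANDOM_{i:03d}"] = [str(g) for g in members]
    return sets


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """A complete cohort: volumes, masks, counts, labels, sets, truth."""
    case_ids = [f"case_{i:03d}" for i in range(config.n_cases)]
    stages = ["intra"] * config.n_intra + ["extra"] * config.n_extra
    labels = pd.Series(stages, index=case_ids, name="stage")

    tex_scales, gen_scales = phenotype_scales(config)
    volumes, masks = [], []
    for i, stage in enumerate(stages):
        vol, msk = generate_tumor_volume(
            stage, config, case_seed=i, effect_scale=float(tex_scales[i]) or 1.0
        )
        vol.case_id = case_ids[i]
        msk.case_id = case_ids[i]
        volumes.append(vol)
        masks.append(msk)

    counts, counts_truth = generate_counts(config, labels, effect_scales=gen_scales)
    gene_sets = generate_gene_sets(counts_truth, config)

    truth = {
        "planted_degs": counts_truth["planted_degs"],
        "size_factors": counts_truth["size_factors"],
        "enriched_sets": [s for s in gene_sets if s.startswith("SIG_UP_")],
        "phenotype_scales": {
            "texture": {c: float(v) for c, v in zip(case_ids, tex_scales)},
            "expression": {c: float(v) for c, v in zip(case_ids, gen_scales)},
        },
        "texture": (
            {
                "effect": config.texture_effect,
                "intra_sigma": 0.8,
                "extra_sigma": 0.8 * (1.0 + config.texture_effect),
            }
            if config.texture_effect > 0
            else {}
        ),
        "gene_sets": gene_sets,
    }
    return SyntheticCohort(
        config=config,
        case_ids=case_ids,
        labels=labels,
        volumes=volumes,
        masks=masks,
        counts=counts,
        truth=truth,
    )
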