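"""Synthetic study generator.

Builds a fully synthetic cohort — healthy controls plus people with MS in
three cognitive phenotypes — with the statistical structure the downstream
analysis assumes: a block-based toy parcellation (212 regions, 7 networks),
per-subject FA/MD/partial-volume maps, network-targeted cortical lesion
masks, and a cohort table with demographics, EDSS, MS subtype and seven
neuropsychological domain scores. Latent truth (phenotype labels, effect
sizes) is kept for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, ParcellationAtlas
from .config import DOMAINS, MS_PHENOTYPES, MS_SUBTYPES, PHENOTYPES, SimulationConfig
from .errors import AtlasError, ConfigError

_BLOCK = 3  # toy regions are BLOCK^3 axis-aligned cubes


@dataclass
class SubjectImageSet:
    """Per-subject maps on the atlas grid: FA, MD, PV fraction, CL mask."""

    subject: str
    phenotype: str
    fa: np.ndarray
    md: np.ndarray
    pv: np.ndarray
    cl_mask: np.ndarray


@dataclass
class SyntheticStudy:
    """A complete simulated study bundle."""

    atlas: ParcellationAtlas
    images: dict[str, SubjectImageSet]
    cohort: pd.DataFrame
    config: SimulationConfig
    true_effects: dict = field(default_factory=dict)

    @property
    def hc_subjects(self) -> list[str]:
        return list(self.cohort.index[self.cohort["group"] == "HC"])

    @property
    def ms_subjects(self) -> list[str]:
        return list(self.cohort.index[self.cohort["group"] == "MS"])


# ----------------------------------------------------------------------
def make_toy_atlas(config: SimulationConfig) -> ParcellationAtlas:
    """Tile the grid with ``BLOCK^3`` cubes and label the first n_regions.

    Regions are assigned round-robin to the seven networks and alternately
    to the two hemispheres; geometry carries no meaning beyond giving every
    region >= 8 voxels and well-defined boundaries for the PV taper.
    """
    nx, ny, nz = config.grid_shape
    sites = [
        (i, j, k)
        for i in range(nx // _BLOCK)
        for j in range(ny // _BLOCK)
        for k in range(nz // _BLOCK)
    ]
    if len(sites) < config.n_regions:
        raise AtlasError(
            f"grid {config.grid_shape} hosts at most {len(sites)} regions "
            f"of {_BLOCK}^3 voxels; {config.n_regions} requested"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int32)
    networks: dict[int, str] = {}
    hemis: dict[int, str] = {}
    for idx in range(config.n_regions):
        rid = idx + 1
        i, j, k = sites[idx]
        labels[
            i * _BLOCK : (i + 1) * _BLOCK,
            j * _BLOCK : (j + 1) * _BLOCK,
            k * _BLOCK : (k + 1) * _BLOCK,
        ] = rid
        if config.region_network_map is not None:
            networks[rid] = config.region_network_map[rid]
        else:
            networks[rid] = config.networks[idx % len(config.networks)]
        hemis[rid] = HEMISPHERES[idx % 2]
    return ParcellationAtlas(
        labels=labels,
        voxel_size=config.voxel_size,
        region_networks=networks,
        region_hemispheres=hemis,
    )


def partial_volume_map(atlas: ParcellationAtlas, boundary: float = 0.7) -> np.ndarray:
    """PV fraction: 1.0 in region cores, ``boundary`` at boundary voxels.

    A voxel is boundary when any 6-neighbour (or the volume edge) carries a
    different label. Background is 0.
    """
    lab = atlas.labels
    core = lab > 0
    for axis in range(3):
        for shift in (1, -1):
            nb = np.full_like(lab, -1)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            nb[tuple(dst)] = lab[tuple(src)]
            core &= nb == lab
    pv = np.where(lab > 0, boundary, 0.0)
    pv[core] = 1.0
    return pv.astype(np.float32)


# ----------------------------------------------------------------------
def simulate_subject_images(
    atlas: ParcellationAtlas,
    phenotype: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject: str = "sub",
) -> SubjectImageSet:
    """Draw one subject's FA/MD/PV maps and CL mask.

    Voxel values are region baseline + phenotype/network MD shift +
    a per-subject regional random effect + voxelwise Gaussian noise.
    Lesions are spheres placed inside cortex with network-specific Poisson
    counts (HC: none); regions touched by a lesion additionally receive the
    configured lesional FA/MD shifts over their whole extent.
    """
    if phenotype not in PHENOTYPES:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    lab = atlas.labels
    ids = atlas.region_ids
    base = config.region_baselines()
    shift_md = np.zeros(ids.size)
    net_shift = config.nonlesional_md_effect.get(phenotype, {})
    for pos, rid in enumerate(ids):
        shift_md[pos] = net_shift.get(atlas.region_networks[int(rid)], 0.0)

    # per-subject regional random effects (between-subject variability)
    eff_fa = rng.normal(0.0, config.hc_region_sds["fa"], ids.size)
    eff_md = rng.normal(0.0, config.hc_region_sds["md"], ids.size)
    fa_region = base["fa"].to_numpy()[ids - 1] + eff_fa
    md_region = base["md"].to_numpy()[ids - 1] + shift_md + eff_md

    # lesions first so lesional shifts can be folded into region values
    cl_mask, _ = draw_lesions(atlas, phenotype, config, rng)
    lesional = np.unique(lab[cl_mask > 0])
    lesional = lesional[lesional > 0]
    if lesional.size:
        hit = np.isin(ids, lesional)
        fa_region[hit] += config.lesional_effect["fa"]
        md_region[hit] += config.lesional_effect["md"]

    # paint regions into voxel maps, add voxel noise inside cortex
    pos_of = np.zeros(int(ids.max()) + 1, dtype=np.int64)
    pos_of[ids] = np.arange(ids.size)
    inside = lab > 0
    fa = np.zeros(lab.shape, dtype=np.float32)
    md = np.zeros(lab.shape, dtype=np.float32)
    fa[inside] = fa_region[pos_of[lab[inside]]]
    md[inside] = md_region[pos_of[lab[inside]]]
    n_in = int(inside.sum())
    if config.voxel_noise["fa"] > 0:
        fa[inside] += rng.normal(0.0, config.voxel_noise["fa"], n_in)
    if config.voxel_noise["md"] > 0:
        md[inside] += rng.normal(0.0, config.voxel_noise["md"], n_in)
    np.clip(fa, 0.0, 1.0, out=fa)
    np.clip(md, 1e-6, None, out=md)
    md[~inside] = 0.0

    pv = partial_volume_map(atlas, config.pv_boundary)
    return SubjectImageSet(subject, phenotype, fa, md, pv, cl_mask)


def draw_lesions(
    atlas: ParcellationAtlas,
    phenotype: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, int]]:
    """Network-targeted spherical CLs, clipped to cortex. HC gets none.

    Returns the mask and the per-network lesion counts actually drawn
    (before spatial overlap), which drive the topography statistics.
    """
    mask = np.zeros(atlas.labels.shape, dtype=np.uint8)
    nets = list(config.lesion_rate_by_network)
    if phenotype == "HC":
        return mask, {n: 0 for n in nets}
    if rng.random() >= config.cl_presence_by_phenotype[phenotype]:
        return mask, {n: 0 for n in nets}  # lesion-free MS subject
    scale = config.lesion_scale_by_phenotype[phenotype]
    rates = np.array([config.lesion_rate_by_network[n] for n in nets])
    counts = rng.poisson(rates * scale)
    if counts.sum() == 0:  # presence was drawn, so force at least one CL
        counts[rng.choice(len(nets), p=rates / rates.sum())] = 1

    lab = atlas.labels
    net_voxels = _network_voxels(atlas)
    rlo, rhi = config.lesion_radius_range
    shape = lab.shape
    for n, c in zip(nets, counts):
        vox = net_voxels.get(n)
        if vox is None or vox.shape[0] == 0:
            continue
        for _ in range(int(c)):
            center = vox[rng.integers(vox.shape[0])]
            radius = int(rng.integers(rlo, rhi + 1))
            sl = tuple(
                slice(max(0, center[a] - radius), min(shape[a], center[a] + radius + 1))
                for a in range(3)
            )
            local = np.indices([s.stop - s.start for s in sl])
            d2 = sum(
                (local[a] + sl[a].start - center[a]) ** 2 for a in range(3)
            )
            sub = mask[sl]
            sub[(d2 <= radius**2) & (lab[sl] > 0)] = 1
    return mask, dict(zip(nets, (int(c) for c in counts)))


def _network_voxels(atlas: ParcellationAtlas) -> dict[str, np.ndarray]:
    """Voxel coordinates per network, cached on the atlas instance."""
    cached = atlas.__dict__.get("_net_voxels")
    if cached is not None:
        return cached
    lab = atlas.labels
    out: dict[str, np.ndarray] = {}
    for n in set(atlas.region_networks.values()):
        rids = [r for r, nn in atlas.region_networks.items() if nn == n]
        out[n] = np.argwhere(np.isin(lab, rids))
    object.__setattr__(atlas, "_net_voxels", out)
    return out


# ----------------------------------------------------------------------
def simulate_cognition(
    phenotype: str,
    covariates: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.Series:
    """Draw the seven domain Z-scores for one subject.

    Scores center on the phenotype-specific domain means, with a covariate
    adjustment (older / male / lower-education subjects score worse) that is
    centered within phenotype so the group means are preserved.
    """
    if phenotype not in PHENOTYPES:
        raise ConfigError(f"unknown phenotype {phenotype!r}")
    cov = config.covariate_model
    eff = cov["effects"]
    ce = (
        eff["age_per_year"] * (covariates["age"] - cov["age"][phenotype][0])
        + eff["female"] * (covariates["sex_female"] - cov["sex_female"][phenotype])
        + eff["educ_high"] * (covariates["educ_high"] - cov["educ_high"][phenotype])
    )
    vals = {}
    for d in DOMAINS:
        mean, sd = config.domain_effects[phenotype][d]
        vals[d] = mean + ce + rng.normal(0.0, sd)
    return pd.Series(vals, name="domain_z")


# ----------------------------------------------------------------------
def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate the full study: atlas, all subject images, cohort table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    atlas = make_toy_atlas(config)
    counts = config.group_counts()

    roster: list[tuple[str, str, str]] = []  # (subject, group, phenotype)
    for i in range(config.n_hc):
        roster.append((f"HC{i + 1:03d}", "HC", "HC"))
    k = 0
    for ph in MS_PHENOTYPES:
        for _ in range(counts[ph]):
            k += 1
            roster.append((f"MS{k:03d}", "MS", ph))

    cov_model = config.covariate_model
    images: dict[str, SubjectImageSet] = {}
    rows = []
    for subject, group, ph in roster:
        age = float(np.clip(rng.normal(*cov_model["age"][ph]), 25, 80))
        sex_female = int(rng.random() < cov_model["sex_female"][ph])
        educ_high = int(rng.random() < cov_model["educ_high"][ph])
        covs = {"age": age, "sex_female": sex_female, "educ_high": educ_high}
        images[subject] = simulate_subject_images(atlas, ph, config, rng, subject)
        scores = simulate_cognition(ph, covs, config, rng)
        if group == "MS" and config.domain_missing_rate > 0:
            miss = rng.random(len(DOMAINS)) < config.domain_missing_rate
            while miss.sum() > len(DOMAINS) - 2:  # keep >= 2 domains scorable
                miss = rng.random(len(DOMAINS)) < config.domain_missing_rate
            scores[np.asarray(miss)] = np.nan
        row = {
            "group": group,
            "phenotype_true": ph,
            "age": age,
            "sex_female": sex_female,
            "educ_high": educ_high,
        }
        if group == "MS":
            mu, sd = config.edss_model[ph]
            edss = float(np.clip(np.round(rng.normal(mu, sd) * 2) / 2, 1.5, 8.0))
            row["edss"] = edss
            row["ms_subtype"] = MS_SUBTYPES[
                rng.choice(3, p=np.asarray(config.subtype_probs[ph]))
            ]
        else:
            row["edss"] = np.nan
            row["ms_subtype"] = ""
        for d in DOMAINS:
            row[f"score_{d}"] = scores[d]
        rows.append(pd.Series(row, name=subject))

    cohort = pd.DataFrame(rows)
    cohort.index.name = "subject"
    true_effects = {
        "nonlesional_md_ci_minus_cp_dmn": (
            config.nonlesional_md_effect["CI"]["DMN"]
            - config.nonlesional_md_effect["CP"]["DMN"]
        ),
        "lesional_md_shift": config.lesional_effect["md"],
        "lesional_fa_shift": config.lesional_effect["fa"],
        "target_cl_prevalence": config.target_cl_prevalence,
    }
    return SyntheticStudy(atlas, images, cohort, config, true_effects)
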