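"""Simulation configuration: the generative counterpart of the study design.

The defaults encode the cohort the analysis assumes: 48 healthy controls
(HC) and 176 people with MS split into cognitively preserved (CP, n=95),
mildly cognitively impaired (mildly CI, n=37) and cognitively impaired
(CI, n=44); a 212-region / 7-network parcellation; healthy cortical mean
diffusivity (MD) near 1.02e-3 mm^2/s with a between-subject SD of 0.04 and
fractional anisotropy (FA) near 0.18 (SD 0.01); cortical lesions (CLs) in
87.5% of MS subjects with network-specific rates highest in the ventral
attention and default mode networks; and a CI-specific non-lesional MD
increase confined to the DMN, FPN and SMN.

All MD values in this package are in units of 1e-3 mm^2/s.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .atlas import NETWORKS
from .errors import ConfigError

#: Cognitive phenotypes of people with MS, ordered from preserved to impaired.
MS_PHENOTYPES = ("CP", "mildly_CI", "CI")

#: All subject groups the simulator knows.
PHENOTYPES = ("HC",) + MS_PHENOTYPES

#: The seven neuropsychological domains, in a fixed order.
DOMAINS = (
    "attention",
    "information_processing_speed",
    "verbal_memory",
    "visuospatial_memory",
    "working_memory",
    "ef_inhibition",
    "ef_flexibility_fluency",
)

# Per-domain (mean, SD) of domain Z-scores by phenotype. HC is the scoring
# reference, so its means are 0 by construction; SDs differ per domain
# because the underlying test batteries do.
_DOMAIN_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "HC": {
        "attention": (0.00, 0.60),
        "information_processing_speed": (0.00, 1.00),
        "verbal_memory": (0.00, 0.89),
        "visuospatial_memory": (0.00, 0.95),
        "working_memory": (0.00, 1.00),
        "ef_inhibition": (0.00, 1.00),
        "ef_flexibility_fluency": (0.00, 0.77),
    },
    "CP": {
        "attention": (-0.41, 0.63),
        "information_processing_speed": (-0.67, 1.06),
        "verbal_memory": (0.06, 0.93),
        "visuospatial_memory": (-0.24, 1.04),
        "working_memory": (-0.06, 0.92),
        "ef_inhibition": (0.04, 1.25),
        "ef_flexibility_fluency": (-0.05, 0.75),
    },
    "mildly_CI": {
        "attention": (-1.52, 0.80),
        "information_processing_speed": (-2.03, 0.96),
        "verbal_memory": (-0.98, 0.79),
        "visuospatial_memory": (-0.64, 0.91),
        "working_memory": (-0.36, 1.40),
        "ef_inhibition": (-0.61, 1.10),
        "ef_flexibility_fluency": (-0.34, 0.67),
    },
    "CI": {
        "attention": (-1.99, 1.48),
        "information_processing_speed": (-2.81, 1.29),
        "verbal_memory": (-1.39, 0.96),
        "visuospatial_memory": (-1.45, 1.15),
        "working_memory": (-1.03, 1.67),
        "ef_inhibition": (-1.58, 1.45),
        "ef_flexibility_fluency": (-1.76, 1.49),
    },
}

# Covariate distributions by phenotype: age ~ Normal(mean, sd), sex and
# education are Bernoulli. Effects on cognition are centered within
# phenotype so the group-level domain means above are preserved.
_COVARIATE_MODEL = {
    "age": {
        "HC": (50.83, 7.04),
        "CP": (53.45, 8.98),
        "mildly_CI": (54.73, 8.87),
        "CI": (55.53, 9.63),
    },
    "sex_female": {"HC": 0.563, "CP": 0.674, "mildly_CI": 0.676, "CI": 0.659},
    "educ_high": {"HC": 0.542, "CP": 0.442, "mildly_CI": 0.432, "CI": 0.341},
    # additive domain-Z effects; older / male / lower education do worse
    "effects": {"age_per_year": -0.02, "female": 0.25, "educ_high": 0.30},
}

# Expected CL count per network for a CP subject who has any CL at all;
# multiplied by the phenotype scale below. Ordering reflects the observed
# topography: VAN carries the highest load relative to network volume,
# followed by DMN and limbic; visual is least affected. (In this generator
# network volumes are near-equal, so the rate ordering directly sets the
# fraction ordering.)
_LESION_RATES = {
    "VAN": 2.0,
    "limbic": 1.2,
    "DMN": 1.1,
    "SMN": 0.8,
    "DAN": 0.7,
    "FPN": 0.7,
    "visual": 0.3,
}

_LESION_SCALE = {"CP": 1.0, "mildly_CI": 2.0, "CI": 2.5}

# Probability that an MS subject has >= 1 CL; weighted by the default group
# mix these give an overall CL prevalence of 154/176 = 87.5%.
_CL_PRESENCE = {"CP": 80 / 95, "mildly_CI": 35 / 37, "CI": 39 / 44}

# Non-lesional cortical MD shift (1e-3 mm^2/s) added on top of the healthy
# baseline, by phenotype and network. The CI excess over CP (+0.04) is
# confined to DMN, FPN and SMN; elsewhere CI matches CP.
_CI_TARGET_NETWORKS = ("DMN", "FPN", "SMN")


def _nonlesional_md_effects() -> dict[str, dict[str, float]]:
    eff: dict[str, dict[str, float]] = {"HC": {n: 0.0 for n in NETWORKS}}
    eff["CP"] = {n: 0.03 for n in NETWORKS}
    eff["mildly_CI"] = {n: 0.05 for n in NETWORKS}
    eff["CI"] = {n: (0.07 if n in _CI_TARGET_NETWORKS else 0.03) for n in NETWORKS}
    return eff


# EDSS (ordinal disability, 1.5-8 in steps of 0.5) and MS-subtype
# (RR/SP/PP) generators by phenotype.
_EDSS_MODEL = {"CP": (3.2, 1.3), "mildly_CI": (4.2, 1.3), "CI": (4.6, 1.3)}
_SUBTYPE_PROBS = {
    "CP": (0.684, 0.200, 0.116),
    "mildly_CI": (0.568, 0.297, 0.135),
    "CI": (0.568, 0.273, 0.159),
}
MS_SUBTYPES = ("RR", "SP", "PP")

# Internal RNG seed for the fixed per-region healthy baselines. This is part
# of the study definition (regional heterogeneity pattern), deliberately
# decoupled from the sampling seed so that changing `seed` re-draws subjects
# but not the "anatomy".
_BASELINE_SEED = 271828


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic study.

    Counts, mixing proportions, imaging grid, healthy baselines, lesion
    topography rates, diffusion effect sizes and the cognitive/covariate
    model. ``seed`` drives every random draw; identical config + seed gives
    bit-identical studies.
    """

    n_hc: int = 48
    n_ms: int = 176
    #: proportions over (CP, mildly_CI, CI); defaults give 95/37/44 of 176
    group_mix: tuple[float, float, float] = (95 / 176, 37 / 176, 44 / 176)
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_regions: int = 212
    networks: tuple[str, ...] = NETWORKS
    #: optional explicit region -> network map; round-robin when None
    region_network_map: dict[int, str] | None = None
    #: per-region healthy (mean FA, mean MD); generated when None
    hc_region_means: pd.DataFrame | None = None
    #: between-subject SD of regional FA / MD in controls
    hc_region_sds: dict[str, float] = field(
        default_factory=lambda: {"fa": 0.01, "md": 0.04}
    )
    #: within-region voxelwise noise SD
    voxel_noise: dict[str, float] = field(
        default_factory=lambda: {"fa": 0.005, "md": 0.01}
    )
    #: band in which generated MD baselines must lie (1e-3 mm^2/s)
    md_baseline_band: tuple[float, float] = (0.94, 1.10)
    lesion_rate_by_network: dict[str, float] = field(
        default_factory=lambda: dict(_LESION_RATES)
    )
    lesion_scale_by_phenotype: dict[str, float] = field(
        default_factory=lambda: dict(_LESION_SCALE)
    )
    cl_presence_by_phenotype: dict[str, float] = field(
        default_factory=lambda: dict(_CL_PRESENCE)
    )
    lesion_radius_range: tuple[int, int] = (1, 3)
    #: additive (FA, MD) shift applied throughout lesional regions
    lesional_effect: dict[str, float] = field(
        default_factory=lambda: {"fa": 0.01, "md": 0.03}
    )
    nonlesional_md_effect: dict[str, dict[str, float]] = field(
        default_factory=_nonlesional_md_effects
    )
    domain_effects: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DOMAIN_EFFECTS.items()}
    )
    covariate_model: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _COVARIATE_MODEL.items()}
    )
    #: per-domain missingness probability for MS subjects
    domain_missing_rate: float = 0.02
    edss_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_EDSS_MODEL)
    )
    subtype_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_SUBTYPE_PROBS)
    )
    #: partial-volume fraction at region-boundary voxels (cores are 1.0)
    pv_boundary: float = 0.7
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_hc <= 0 or self.n_ms <= 0:
            raise ConfigError("subject counts must be positive")
        if abs(sum(self.group_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.group_mix):
            raise ConfigError("group_mix must be nonnegative and sum to 1")
        if self.n_regions < len(self.networks):
            raise ConfigError("need at least one region per network")
        if any(s <= 0 for s in self.hc_region_sds.values()):
            raise ConfigError("hc_region_sds must be strictly positive")
        lo, hi = self.md_baseline_band
        means = self.region_baselines()["md"]
        if means.min() < lo or means.max() > hi:
            raise ConfigError(
                f"MD baselines outside plausible band [{lo}, {hi}]"
            )
        if not 0.0 <= self.pv_boundary <= 1.0:
            raise ConfigError("pv_boundary must lie in [0, 1]")

    def region_baselines(self) -> pd.DataFrame:
        """Per-region healthy (FA, MD) means, indexed by region id 1..n.

        Generated once from a fixed internal seed when not supplied, so the
        regional heterogeneity pattern is stable across sampling seeds.
        """
        if self.hc_region_means is not None:
            return self.hc_region_means
        rng = np.random.default_rng(_BASELINE_SEED)
        ids = np.arange(1, self.n_regions + 1)
        md = np.clip(rng.normal(1.02, 0.015, self.n_regions), *self.md_baseline_band)
        fa = np.clip(rng.normal(0.18, 0.008, self.n_regions), 0.12, 0.25)
        return pd.DataFrame({"fa": fa, "md": md}, index=ids)

    def group_counts(self) -> dict[str, int]:
        """Integer subgroup sizes from ``group_mix`` by largest remainder."""
        raw = np.asarray(self.group_mix) * self.n_ms
        base = np.floor(raw).astype(int)
        rem = self.n_ms - base.sum()
        order = np.argsort(-(raw - base))
        base[order[:rem]] += 1
        return dict(zip(MS_PHENOTYPES, (int(x) for x in base)))

    @property
    def target_cl_prevalence(self) -> float:
        """Expected fraction of MS subjects with >= 1 CL under the defaults."""
        counts = self.group_counts()
        total = sum(counts.values())
        return sum(
            counts[g] * self.cl_presence_by_phenotype[g] for g in MS_PHENOTYPES
        ) / total

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.hc_region_means is not None:
            d["hc_region_means"] = {
                "index": self.hc_region_means.index.tolist(),
                "fa": self.hc_region_means["fa"].tolist(),
                "md": self.hc_region_means["md"].tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("hc_region_means") is not None:
            m = d["hc_region_means"]
            d["hc_region_means"] = pd.DataFrame(
                {"fa": m["fa"], "md": m["md"]}, index=m["index"]
            )
        for key in ("group_mix", "grid_shape", "voxel_size", "networks",
                    "md_baseline_band", "lesion_radius_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("edss_model", "subtype_probs", "domain_effects"):
            if key in d and d[key] is not None:
                d[key] = {
                    g: ({k: tuple(v) for k, v in val.items()}
                        if isinstance(val, dict) else tuple(val))
                    for g, val in d[key].items()
                }
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert numpy / tuple values to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
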