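"""Synthetic cohorts with known age-by-diagnosis structure.

The generator emulates the study conditions the analysis is designed for: a
cross-sectional case-control cohort (175 drug-naive patients, 155 controls,
ages 16-60 with a right-skewed distribution putting ~75% of subjects under
36), FA-weighted modular connectomes over the 8-system parcellation, and —
through an :class:`EffectSpec` — group-specific linear age trends injected
into within-system edge strength.  Effects act on edge weights, never on
controllability values directly, so recovering them exercises the full
stabilization -> Gramian -> GLM chain.

Everything is a pure function of (config, effect spec, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from .atlas import SYSTEMS, Parcellation, SystemAssignment
from .connectome import Connectome, write_connectome
from .controllability import controllability_table

#: Generator-internal age centering (cohort midpoint, years); slopes and
#: offsets in an EffectSpec are interpreted relative to this age.
AGE_CENTER = 38.0
WEIGHT_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class SystemEffect:
    """Linear age trend of within-system edge strength for one system.

    Slopes are fractional change per year of age (e.g. -0.004 means within-
    system edges lose 0.4% of their weight per year); ``group_offset`` is a
    fractional baseline shift applied to SCZ subjects at any age.
    """

    slope_hc: float = 0.0
    slope_scz: float = 0.0
    group_offset: float = 0.0


@dataclass(frozen=True)
class EffectSpec:
    """Per-system injected effects plus multiplicative edge noise."""

    systems: dict[str, SystemEffect] = field(default_factory=dict)
    noise_sd: float = 0.05

    def effect(self, system: str) -> SystemEffect:
        return self.systems.get(system, SystemEffect())

    def to_dict(self) -> dict:
        return {
            "noise_sd": self.noise_sd,
            "systems": {
                s: dataclasses.asdict(e) for s, e in sorted(self.systems.items())
            },
        }


def null_effect_spec(noise_sd: float = 0.05) -> EffectSpec:
    """No age trends, no group offsets: the null condition."""
    return EffectSpec({}, noise_sd)


def dmn_decline_spec(slope_hc: float = -0.005, noise_sd: float = 0.05) -> EffectSpec:
    """HC-only decline of within-DMN edge strength with age; SCZ flat.

    The default slope (-0.5%/yr) was fixed by calibration: it induces a
    moderate system-level trajectory contrast (HC partial r around -0.4 to
    -0.6 at n = 330, patients flat) that the interaction battery detects
    reliably without being ceiling-level.
    """
    return EffectSpec({"DMN": SystemEffect(slope_hc=slope_hc)}, noise_sd)


def study_pattern_spec(noise_sd: float = 0.05) -> EffectSpec:
    """The qualitative pattern reported for this design: age-related DMN
    decline in controls only, and subcortical decline in patients only, with
    a small negative DMN baseline offset in patients."""
    return EffectSpec(
        {
            "DMN": SystemEffect(slope_hc=-0.004, group_offset=-0.03),
            "SUBCORTICAL": SystemEffect(slope_scz=-0.004),
        },
        noise_sd,
    )


@dataclass(frozen=True)
class GroupDemographics:
    n: int
    age_gamma_shape: float
    age_gamma_scale: float
    male_fraction: float
    education_mean: float
    education_sd: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort and connectome generation parameters.

    The demographic defaults target the study's marginal distributions:
    ages with mean ~28.7/27.0 and SD ~11 per group (gamma-distributed above
    16, truncated at 60, giving roughly a 75/25 young/old split around 35),
    the observed sex ratios, education 11.6/12.4 +/- 3.5 years, PANSS
    total 89.95 +/- 16.20 (positive 24.63 +/- 6.31, negative 19.22 +/- 8.01,
    general 46.11 +/- 9.18), GAF 30.19 +/- 10.87, and log-normal DUP with
    mean 33.9 and SD 74.6 months.
    """

    scz: GroupDemographics = GroupDemographics(175, 1.363, 9.303, 81 / 175, 11.61, 3.54)
    hc: GroupDemographics = GroupDemographics(155, 0.936, 11.774, 71 / 155, 12.41, 3.44)
    # clinical score distributions (SCZ only): mean, sd, clip range
    panss_total: tuple = (89.95, 16.20, 30.0, 210.0)
    panss_pos: tuple = (24.63, 6.31, 7.0, 49.0)
    panss_neg: tuple = (19.22, 8.01, 7.0, 49.0)
    panss_general: tuple = (46.11, 9.18, 16.0, 112.0)
    gaf: tuple = (30.19, 10.87, 1.0, 100.0)
    dup_lognorm_mu: float = 2.6433  # matches mean 33.92, SD 74.56 months
    dup_lognorm_sigma: float = 1.3282
    # connectome backbone: modular with denser/stronger within-system edges
    atlas: str = "full"  # "full" (234 nodes) or "toy" (20 nodes)
    p_within: float = 0.7
    p_between: float = 0.3
    fa_beta_a: float = 9.0  # FA ~ Beta(9, 11): mean 0.45, sd ~0.11
    fa_beta_b: float = 11.0
    seed: int = 0

    def load_atlas(self) -> tuple[Parcellation, SystemAssignment]:
        if self.atlas == "toy":
            return atlas_mod.load_toy_atlas()
        return atlas_mod.load_default_atlas()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for grp in ("scz", "hc"):
            if isinstance(d.get(grp), dict):
                d[grp] = GroupDemographics(**d[grp])
        for key in ("panss_total", "panss_pos", "panss_neg", "panss_general", "gaf"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), f)


def toy_config(n_scz: int = 175, n_hc: int = 155, seed: int = 0) -> GeneratorConfig:
    """Default configuration on the reduced 20-node atlas."""
    cfg = GeneratorConfig(atlas="toy", seed=seed)
    return dataclasses.replace(
        cfg,
        scz=dataclasses.replace(cfg.scz, n=n_scz),
        hc=dataclasses.replace(cfg.hc, n=n_hc),
    )


# ---------------------------------------------------------------------------
# subjects


def _truncated_ages(rng, n, shape, scale):
    ages = np.empty(n)
    filled = 0
    while filled < n:
        draw = 16.0 + rng.gamma(shape, scale, size=2 * (n - filled))
        draw = draw[draw <= 60.0]
        take = min(len(draw), n - filled)
        ages[filled : filled + take] = draw[:take]
        filled += take
    return ages


def _clipped_normal(rng, n, mean, sd, lo, hi):
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def generate_subjects(config: GeneratorConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw the demographic/clinical cohort table (no connectomes)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for dx, grp in (("SCZ", config.scz), ("HC", config.hc)):
        n = grp.n
        if n == 0:
            continue
        ages = _truncated_ages(rng, n, grp.age_gamma_shape, grp.age_gamma_scale)
        n_male = int(round(grp.male_fraction * n))
        sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
        rng.shuffle(sex)
        edu = np.round(
            _clipped_normal(rng, n, grp.education_mean, grp.education_sd, 0.0, 22.0), 1
        )
        frame = pd.DataFrame(
            {
                "subject_id": [f"{dx.lower()}{i:04d}" for i in range(n)],
                "diagnosis": dx,
                "age": np.round(ages, 2),
                "sex": sex,
                "education": edu,
            }
        )
        if dx == "SCZ":
            frame["dup"] = np.round(
                rng.lognormal(config.dup_lognorm_mu, config.dup_lognorm_sigma, n), 1
            )
            for col in ("panss_total", "panss_pos", "panss_neg", "panss_general", "gaf"):
                mean, sd, lo, hi = getattr(config, col)
                frame[col] = np.round(_clipped_normal(rng, n, mean, sd, lo, hi), 1)
        else:
            for col in ("dup", "panss_total", "panss_pos", "panss_neg", "panss_general", "gaf"):
                frame[col] = np.nan
        frames.append(frame)
    if not frames:
        raise ValueError("config yields an empty cohort")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# connectomes


@dataclass(frozen=True)
class BaseTopology:
    """Cohort-shared backbone: edge mask and baseline FA weights."""

    weights: np.ndarray  # symmetric, zero where no edge
    system_of: tuple[str, ...]


def base_topology(
    config: GeneratorConfig, assignment: SystemAssignment, seed: int | None = None
) -> BaseTopology:
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    system_of = assignment.system_of
    n = len(system_of)
    same = np.array(
        [[system_of[i] == system_of[j] for j in range(n)] for i in range(n)]
    )
    p = np.where(same, config.p_within, config.p_between)
    mask = rng.random((n, n)) < p
    w = rng.beta(config.fa_beta_a, config.fa_beta_b, size=(n, n))
    w = np.triu(np.where(mask, w, 0.0), k=1)
    w = w + w.T
    return BaseTopology(w, tuple(system_of))


def generate_connectome(
    subject: pd.Series,
    effect_spec: EffectSpec,
    base: BaseTopology,
    seed: int,
) -> Connectome:
    """Apply the subject's injected effects and noise to the base backbone.

    Within-system edges of system s are scaled by
    ``1 + slope_group(s) * (age - 38) + group_offset(s) * [SCZ]`` and every
    present edge by multiplicative noise ``1 + noise_sd * N(0, 1)``; results
    are clamped to [0.05, 0.95].
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    n = base.weights.shape[0]
    age_c = float(subject["age"]) - AGE_CENTER
    is_scz = subject["diagnosis"] == "SCZ"
    scale = np.ones((n, n))
    for s in SYSTEMS:
        eff = effect_spec.effect(s)
        slope = eff.slope_scz if is_scz else eff.slope_hc
        factor = 1.0 + slope * age_c + (eff.group_offset if is_scz else 0.0)
        members = [i for i, sys_ in enumerate(base.system_of) if sys_ == s]
        if members:
            ix = np.ix_(members, members)
            scale[ix] = factor
    noise = 1.0 + effect_spec.noise_sd * rng.standard_normal((n, n))
    noise = np.triu(noise, k=1)
    noise = noise + noise.T + np.eye(n)
    w = base.weights * scale * noise
    present = base.weights > 0
    clipped = present & ((w < WEIGHT_CLIP[0]) | (w > WEIGHT_CLIP[1]))
    if present.sum() and clipped.sum() / present.sum() > 0.20:
        import logging

        logging.getLogger(__name__).warning(
            "effect spec clamps %.0f%% of edges for subject %s",
            100 * clipped.sum() / present.sum(),
            subject["subject_id"],
        )
    w = np.where(present, np.clip(w, *WEIGHT_CLIP), 0.0)
    np.fill_diagonal(w, 0.0)
    return Connectome(str(subject["subject_id"]), w)


def _subject_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, index]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def simulate_study(
    config: GeneratorConfig,
    effect_spec: EffectSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and its controllability table fully in memory.

    Returns (cohort table, controllability table); the second is what the
    statistical battery consumes.  This runs the real controllability code on
    every generated connectome — nothing is short-circuited.
    """
    master = config.seed if seed is None else seed
    parc, assignment = config.load_atlas()
    cohort = generate_subjects(config, master)
    base = base_topology(config, assignment, master)
    connectomes = (
        generate_connectome(row, effect_spec, base, _subject_seed(master, i))
        for i, row in cohort.iterrows()
    )
    ctrl = controllability_table(connectomes, parc, assignment)
    return cohort, ctrl


def generate_cohort_dataset(
    config: GeneratorConfig,
    effect_spec: EffectSpec,
    out_dir,
    seed: int | None = None,
    fmt: str = "csv",
) -> Path:
    """Write a complete on-disk dataset: cohort.csv, one connectome file per
    subject, and a manifest with SHA-256 hashes.  Returns the manifest path."""
    out = Path(out_dir)
    (out / "connectomes").mkdir(parents=True, exist_ok=True)
    master = config.seed if seed is None else seed
    _, assignment = config.load_atlas()
    cohort = generate_subjects(config, master)
    base = base_topology(config, assignment, master)

    hashes: dict[str, str] = {}

    def _record(path: Path) -> None:
        hashes[str(path.relative_to(out))] = hashlib.sha256(
            path.read_bytes()
        ).hexdigest()

    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    _record(cohort_path)
    for i, row in cohort.iterrows():
        c = generate_connectome(row, effect_spec, base, _subject_seed(master, i))
        path = out / "connectomes" / f"{row['subject_id']}.{fmt}"
        write_connectome(c, path)
        _record(path)
    manifest = {
        "seed": int(master),
        "config": json.loads(json.dumps(config.to_dict())),
        "effect_spec": effect_spec.to_dict(),
        "n_subjects": int(len(cohort)),
        "files": hashes,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
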