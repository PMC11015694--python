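"""Seeded synthetic cohorts: demographics plus simulated oddball epoch sets.

Each simulated trial is a sum of Gaussian evoked bumps (P2-like near 200 ms,
P3-like near 400 ms) with trial-level amplitude and latency jitter, additive
white noise, occasional super-threshold artifact trials and behavioural
errors.  Trial-level jitter deviations on the right channel (Fp2) are scaled
by a per-group factor so hemispheric asymmetry has a controlled sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import (
    CHANNELS,
    ConfigError,
    EpochSet,
    SubjectProfile,
    canonical_time_axis,
)

__all__ = [
    "ComponentParams",
    "DemographicParams",
    "GroupParams",
    "GeneratorConfig",
    "generate_cohort",
    "simulate_subject_epochs",
    "default_config",
]


@dataclass
class ComponentParams:
    """One evoked Gaussian bump: mean amplitude (µV), mean latency and width (ms)."""

    amplitude: float
    latency: float
    width: float


@dataclass
class DemographicParams:
    age_mean: float = 72.0
    age_sd: float = 6.4
    female_prop: float = 0.5
    education_mean: float = 11.0
    education_sd: float = 4.4
    mmse_mean: float = 27.0
    mmse_sd: float = 2.0
    snsb_means: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(SubjectProfile.SNSB_DOMAINS, 0.0)
    )
    snsb_sds: dict[str, float] = field(
        default_factory=lambda: dict.fromkeys(SubjectProfile.SNSB_DOMAINS, 1.0)
    )


@dataclass
class GroupParams:
    """Generative parameters for one group (CN-like or MCI-like)."""

    components: dict[str, ComponentParams]
    amp_jitter_sd: float = 2.0  # τ_A, µV
    lat_jitter_sd: float = 20.0  # τ_L, ms
    right_channel_jitter_scale: float = 1.0
    demographics: DemographicParams = field(default_factory=DemographicParams)
    # between-subject heterogeneity: subjects draw their own jitter SDs from
    # a lognormal with this coefficient of variation around the group value,
    # and their own component means offset by these SDs
    jitter_subject_cv: float = 0.0
    component_subject_amp_sd: float = 0.0  # µV
    component_subject_lat_sd: float = 0.0  # ms


def _default_components() -> dict[str, ComponentParams]:
    return {
        "P2": ComponentParams(amplitude=6.0, latency=200.0, width=30.0),
        "P3": ComponentParams(amplitude=8.0, latency=420.0, width=60.0),
    }


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    n_cn: int = 10
    n_mci: int = 10
    n_target_trials: int = 64
    n_standard_trials: int = 256
    sampling_rate: float = 250.0
    epoch_span: tuple[float, float] = (-200.0, 800.0)
    groups: dict[str, GroupParams] = field(
        default_factory=lambda: {
            "CN": GroupParams(components=_default_components()),
            "MCI": GroupParams(components=_default_components()),
        }
    )
    noise_sd: float = 5.0
    artifact_rate: float = 0.0
    behavioral_error_rate: float = 0.0
    artifact_threshold: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cn", "n_mci", "n_target_trials", "n_standard_trials"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        lo, hi = self.epoch_span
        if not (lo <= -200.0 and hi >= 800.0):
            raise ConfigError(
                f"epoch_span must contain [-200, 800] ms, got {self.epoch_span}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for name in ("artifact_rate", "behavioral_error_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {r}")
        if self.artifact_threshold <= 0:
            raise ConfigError(
                f"artifact_threshold must be > 0, got {self.artifact_threshold}"
            )
        for gname, gp in self.groups.items():
            if gp.amp_jitter_sd < 0:
                raise ConfigError(f"groups[{gname}].amp_jitter_sd must be >= 0")
            if gp.lat_jitter_sd < 0:
                raise ConfigError(f"groups[{gname}].lat_jitter_sd must be >= 0")
            if gp.right_channel_jitter_scale < 0:
                raise ConfigError(
                    f"groups[{gname}].right_channel_jitter_scale must be >= 0"
                )
            for sname in ("jitter_subject_cv", "component_subject_amp_sd",
                          "component_subject_lat_sd"):
                if getattr(gp, sname) < 0:
                    raise ConfigError(f"groups[{gname}].{sname} must be >= 0")
            for cname, comp in gp.components.items():
                if comp.width <= 0:
                    raise ConfigError(
                        f"groups[{gname}].components[{cname}].width must be > 0"
                    )
                if not lo <= comp.latency <= hi:
                    raise ConfigError(
                        f"groups[{gname}].components[{cname}].latency "
                        f"{comp.latency} outside epoch span {self.epoch_span}"
                    )
            d = gp.demographics
            if not 0.0 <= d.female_prop <= 1.0:
                raise ConfigError(f"groups[{gname}].demographics.female_prop")
            for sname in ("age_sd", "education_sd", "mmse_sd"):
                if getattr(d, sname) < 0:
                    raise ConfigError(f"groups[{gname}].demographics.{sname}")


def default_config(**overrides) -> GeneratorConfig:
    """A :class:`GeneratorConfig` with Table-1-like demographic targets.

    CN and MCI demographic distributions follow the published cohort
    marginals (age 72.1/6.4 vs 73.8/6.5, MMSE 27.7/1.9 vs 26.3/2.7, ...);
    the MCI-like group gets inflated trial jitter and a right-channel
    scale > 1.
    """
    cn_demo = DemographicParams(
        age_mean=72.06, age_sd=6.36, female_prop=0.56,
        education_mean=10.83, education_sd=4.36,
        mmse_mean=27.68, mmse_sd=1.90,
        snsb_means={"attention": 9.71, "language": 0.21, "visuospatial": 0.54,
                    "memory": 0.30, "frontal": 0.23},
        snsb_sds={"attention": 2.19, "language": 0.28, "visuospatial": 0.37,
                  "memory": 0.58, "frontal": 0.57},
    )
    mci_demo = DemographicParams(
        age_mean=73.82, age_sd=6.54, female_prop=0.50,
        education_mean=11.14, education_sd=4.48,
        mmse_mean=26.31, mmse_sd=2.68,
        snsb_means={"attention": 8.54, "language": -0.09, "visuospatial": 0.25,
                    "memory": -0.44, "frontal": -0.24},
        snsb_sds={"attention": 1.94, "language": 0.47, "visuospatial": 1.89,
                  "memory": 0.63, "frontal": 0.70},
    )
    groups = {
        "CN": GroupParams(
            components=_default_components(),
            amp_jitter_sd=2.0, lat_jitter_sd=20.0,
            right_channel_jitter_scale=1.0, demographics=cn_demo,
            jitter_subject_cv=0.4,
            component_subject_amp_sd=1.0, component_subject_lat_sd=10.0,
        ),
        "MCI": GroupParams(
            components=_default_components(),
            amp_jitter_sd=3.0, lat_jitter_sd=30.0,
            right_channel_jitter_scale=1.3, demographics=mci_demo,
            jitter_subject_cv=0.4,
            component_subject_amp_sd=1.0, component_subject_lat_sd=10.0,
        ),
    }
    cfg = GeneratorConfig(groups=groups, **overrides)
    cfg.validate()
    return cfg


def _sample_profile(
    subject_id: str, group: str, demo: DemographicParams, rng: np.random.Generator
) -> SubjectProfile:
    age = float(np.clip(rng.normal(demo.age_mean, demo.age_sd), 45.0, 100.0))
    sex = "F" if rng.random() < demo.female_prop else "M"
    education = float(
        np.clip(rng.normal(demo.education_mean, demo.education_sd), 0.0, 25.0)
    )
    mmse = float(np.clip(round(rng.normal(demo.mmse_mean, demo.mmse_sd)), 0, 30))
    snsb = {
        dom: float(rng.normal(demo.snsb_means[dom], demo.snsb_sds[dom]))
        for dom in SubjectProfile.SNSB_DOMAINS
    }
    return SubjectProfile(
        subject_id=subject_id, group=group, age=age, sex=sex,
        education=education, mmse=mmse, snsb=snsb,
    )


def simulate_subject_epochs(
    profile: SubjectProfile,
    config: GeneratorConfig,
    subject_seed,
) -> EpochSet:
    """Simulate one subject's epoch set.

    Each trial waveform is ``sum_c A_c,i * exp(-(t - mu_c,i)^2 / (2 w_c^2))``
    plus white noise, with ``A_c,i ~ N(A_c, τ_A)`` and ``mu_c,i ~ N(mu_c, τ_L)``.
    On Fp2 the trial-level deviations (not the noise) are multiplied by
    ``right_channel_jitter_scale``.  Artifact trials get one sample forced
    beyond the artifact threshold; behavioural-error trials are flagged
    incorrect.
    """
    if profile.group not in config.groups:
        raise ConfigError(
            f"no generator parameters for group {profile.group!r}"
        )
    gp = config.groups[profile.group]
    rng = np.random.default_rng(subject_seed)
    t = canonical_time_axis(config.sampling_rate, config.epoch_span)
    n_samples = t.size

    n_trials = config.n_target_trials + config.n_standard_trials
    labels = np.array(
        ["target"] * config.n_target_trials + ["standard"] * config.n_standard_trials
    )
    labels = labels[rng.permutation(n_trials)]

    comps = list(gp.components.values())
    # subject-level heterogeneity: own jitter SDs (lognormal, mean 1) and
    # own component means
    if gp.jitter_subject_cv > 0:
        s = np.sqrt(np.log1p(gp.jitter_subject_cv**2))
        jitter_mult = rng.lognormal(mean=-0.5 * s**2, sigma=s)
    else:
        jitter_mult = 1.0
    amp_offsets = rng.normal(0.0, gp.component_subject_amp_sd, size=len(comps))
    lat_offsets = rng.normal(0.0, gp.component_subject_lat_sd, size=len(comps))

    # trial-level deviations, shared between channels before right-side scaling
    d_amp = rng.normal(
        0.0, jitter_mult * gp.amp_jitter_sd, size=(n_trials, len(comps))
    )
    d_lat = rng.normal(
        0.0, jitter_mult * gp.lat_jitter_sd, size=(n_trials, len(comps))
    )

    amplitudes = np.empty((n_trials, len(CHANNELS), n_samples))
    scales = (1.0, gp.right_channel_jitter_scale)  # (Fp1, Fp2)
    for ci, scale in enumerate(scales):
        signal = np.zeros((n_trials, n_samples))
        for k, comp in enumerate(comps):
            amp = comp.amplitude + amp_offsets[k] + scale * d_amp[:, k]
            lat = comp.latency + lat_offsets[k] + scale * d_lat[:, k]
            signal += amp[:, None] * np.exp(
                -((t[None, :] - lat[:, None]) ** 2) / (2.0 * comp.width**2)
            )
        amplitudes[:, ci, :] = signal
    amplitudes += rng.normal(0.0, config.noise_sd, size=amplitudes.shape)

    # artifact injection: overwrite one sample so it is guaranteed super-threshold
    artifact = rng.random(n_trials) < config.artifact_rate
    for i in np.flatnonzero(artifact):
        ch = rng.integers(len(CHANNELS))
        k = rng.integers(n_samples)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        amplitudes[i, ch, k] = sign * (
            config.artifact_threshold + 50.0 + rng.uniform(0.0, 50.0)
        )

    errors = rng.random(n_trials) < config.behavioral_error_rate
    epochs = EpochSet(
        subject_id=profile.subject_id,
        time_axis=t,
        amplitudes=amplitudes,
        stimulus_label=labels,
        correct=~errors,
    )
    epochs.validate()
    return epochs


def generate_cohort(
    config: GeneratorConfig,
) -> list[tuple[SubjectProfile, EpochSet]]:
    """Generate ``n_cn + n_mci`` subjects with profiles and epoch sets.

    Identical ``(config, seed)`` yields bit-identical output: per-subject
    streams are spawned from a single :class:`numpy.random.SeedSequence`.
    """
    config.validate()
    n_total = config.n_cn + config.n_mci
    root = np.random.SeedSequence(config.seed)
    demo_seed, *subject_seeds = root.spawn(n_total + 1)
    demo_rng = np.random.default_rng(demo_seed)

    cohort: list[tuple[SubjectProfile, EpochSet]] = []
    for i in range(n_total):
        group = "CN" if i < config.n_cn else "MCI"
        subject_id = f"S{i + 1:04d}"
        profile = _sample_profile(
            subject_id, group, config.groups[group].demographics, demo_rng
        )
        epochs = simulate_subject_epochs(profile, config, subject_seeds[i])
        cohort.append((profile, epochs))
    return cohort


def with_group_overrides(
    config: GeneratorConfig, group: str, **overrides
) -> GeneratorConfig:
    """Return a config with one group's jitter/scale fields replaced."""
    groups = dict(config.groups)
    groups[group] = replace(groups[group], **overrides)
    return replace(config, groups=groups)
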