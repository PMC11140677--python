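"""Synthetic lysate-array and proteome-array scans with planted truth.

The raw scans behind the published screen are not deposited, so every
downstream stage is exercised against a generative model with the
statistical structure the screen assumes:

* multiplicative log-normal spot noise (coefficient of variation
  ``spot_cv``) on top of a channel- and role-dependent expected signal;
* an additive Gaussian local background, truncated at zero, of which the
  scanner's background column reports the expected level — so net
  intensity carries the background noise;
* one multiplicative scale factor per scan (log-normal,
  ``batch_scale_sd``), the slide-to-slide/batch effect;
* per-clone abundance heterogeneity (log-normal, ``abundance_cv``) in the
  protein-stain channels (total-protein NHS ester and anti-His), which is
  what makes two batches correlate at R² ≈ 0.93 rather than 1;
* planted kinase effects expressed in pooled WT-spot SD units: a clone
  planted at effect *e* in an anti-phosphotyrosine experiment channel has
  its expected net intensity raised by ``e × baseline_mean ×
  sqrt(spot_cv² + batch_scale_sd²)``, i.e. by *e* WT SDs, so the 1.5-SD
  selection criterion is directly exercisable.  Substrate effects on the
  forward-phase array are analogous, in units of the ±ATP floor SD.

Secondary-antibody-only blanks carry a nonspecific floor of
``blank_floor_frac × baseline_mean``.  Foreground/background medians are
rounded to integer scanner counts.  All randomness flows from
``SimConfig.seed`` through per-scan substreams, so outputs are
byte-identical for identical (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .layout_io import (
    DEFAULT_CONTROL_ROW,
    ArrayLayout,
    ArrayScan,
    Role,
    build_layout,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_ecla",
    "simulate_proteome_array",
    "screen_recovery_config",
    "substrate_recovery_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of the synthetic generator.

    Defaults are the study conditions: 4126 duplicate-printed clones in 48
    blocks, three experiment and three blank assays per antibody for the
    lysate screen, duplicate ±ATP assays for the forward-phase array.
    Planted kinase effects map clone name to either a single effect (all
    antibody channels) or an antibody→effect mapping, in WT-SD units.
    """

    n_clones: int = 4126
    n_blocks: int = 48
    block_columns: int = 20
    n_wt_spots_per_block: int = 2
    planted_kinases: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    planted_substrates: Mapping[str, float] = field(default_factory=dict)
    antibodies: tuple[str, ...] = ("pTyr100", "PY20")
    baseline_mean: float = 2000.0
    spot_cv: float = 0.2
    background_mean: float = 100.0
    background_sd: float = 20.0
    batch_scale_sd: float = 0.15
    blank_floor_frac: float = 0.05
    buffer_protein_frac: float = 0.1
    poly_lysine_frac: float = 0.05
    his_floor_frac: float = 0.02
    landmark_level: float = 5.0
    abundance_cv: float = 0.8
    his_positive_fraction: float = 0.938
    n_replicate_assays: int = 3
    n_qc_batches: int = 2
    include_qc_channels: bool = True
    clone_names: tuple[str, ...] | None = None
    seed: int = 0

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        problems = []
        if self.n_clones < 0:
            problems.append("n_clones must be >= 0")
        if self.spot_cv < 0:
            problems.append("spot_cv must be >= 0")
        if self.n_replicate_assays < 2:
            problems.append("n_replicate_assays must be >= 2")
        if self.n_wt_spots_per_block < 1:
            problems.append("n_wt_spots_per_block must be >= 1")
        if not 0.0 <= self.his_positive_fraction <= 1.0:
            problems.append("his_positive_fraction must be in [0, 1]")
        for name, value in self.planted_substrates.items():
            if not math.isfinite(float(value)):
                problems.append(f"planted substrate effect for {name!r} is not finite")
        for name, value in self.planted_kinases.items():
            effects = value.values() if isinstance(value, Mapping) else [value]
            for e in effects:
                if not math.isfinite(float(e)):
                    problems.append(f"planted kinase effect for {name!r} is not finite")
        if self.clone_names is not None:
            missing = [k for k in self.planted_kinases if k not in self.clone_names]
            missing += [k for k in self.planted_substrates if k not in self.clone_names]
            if missing:
                problems.append(
                    "planted name(s) not in clone_names: " + ", ".join(sorted(set(missing)))
                )
        if problems:
            raise ConfigurationError("; ".join(problems))

    # -- derived quantities -------------------------------------------

    @property
    def sd_unit_factor(self) -> float:
        """Relative pooled WT-spot SD: sqrt(spot_cv² + batch_scale_sd²)."""
        return math.sqrt(self.spot_cv**2 + self.batch_scale_sd**2)

    def kinase_effect(self, clone: str, antibody: str) -> float:
        value = self.planted_kinases.get(clone, 0.0)
        if isinstance(value, Mapping):
            return float(value.get(antibody, 0.0))
        return float(value)

    def resolve_names(self, prefix: str = "clone") -> tuple[str, ...]:
        """Planted names first, then generated fillers up to ``n_clones``."""
        if self.clone_names is not None:
            return tuple(self.clone_names)
        planted = list(self.planted_kinases) + [
            s for s in self.planted_substrates if s not in self.planted_kinases
        ]
        if len(planted) > self.n_clones:
            raise ConfigurationError(
                f"{len(planted)} planted names exceed n_clones={self.n_clones}"
            )
        fillers = (f"{prefix}_{i:05d}" for i in range(1, self.n_clones + 1))
        names = list(planted)
        for filler in fillers:
            if len(names) >= self.n_clones:
                break
            names.append(filler)
        return tuple(names)


@dataclass
class SimResult:
    """Simulated scans plus the layout and the planted-truth table.

    ``truth`` has columns (name, channel, effect): planted kinase effects per
    antibody channel, planted substrate effects under ``plus_ATP``, and one
    row per His-expressing clone under ``antiHis`` (effect 1.0).
    """

    scans: list[ArrayScan]
    layout: ArrayLayout
    truth: pd.DataFrame
    config: SimConfig


def _lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise; exactly 1 when sigma == 0."""
    if sigma <= 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def _control_row(cfg: SimConfig) -> tuple[Role, ...]:
    extra = (Role.WT_LYSATE,) * (cfg.n_wt_spots_per_block - 1)
    return extra + DEFAULT_CONTROL_ROW


def _build_sim_layout(cfg: SimConfig, names: Sequence[str]) -> ArrayLayout:
    return build_layout(
        names,
        n_blocks=cfg.n_blocks,
        block_columns=cfg.block_columns,
        control_roles=_control_row(cfg),
    )


def _template_frame(layout: ArrayLayout) -> pd.DataFrame:
    rows = [
        (b, r, c, name, role)
        for (b, r, c), (name, role) in sorted(layout.positions.items())
    ]
    return pd.DataFrame(rows, columns=["block", "row", "column", "name", "role"])


def _expected_levels(
    template: pd.DataFrame,
    antibody: str,
    condition: str,
    cfg: SimConfig,
    abundance: Mapping[str, float],
    expressors: frozenset[str],
    *,
    proteome: bool = False,
) -> np.ndarray:
    """Deterministic expected signal per spot before batch/spot noise."""
    base = cfg.baseline_mean
    u = cfg.sd_unit_factor
    # numpy coerces a str-mixin enum comparand to str(member), so compare on
    # plain value strings
    roles = np.array([Role(r).value for r in template["role"]])
    names = template["name"].to_numpy()
    levels = np.empty(len(template), dtype=float)

    floor = cfg.blank_floor_frac * base
    if condition == "control_no_primary":
        levels[:] = floor
    elif proteome:
        # forward-phase array probed with anti-pTyr: nonspecific floor on
        # every purified protein; planted substrates rise only with ATP
        levels[:] = floor
        levels[roles == Role.BUFFER.value] = 0.2 * floor
        if condition == "plus_ATP":
            for name, effect in cfg.planted_substrates.items():
                levels[names == name] = floor * (1.0 + float(effect) * u)
    elif antibody == "NHS_ester":
        protein_like = np.isin(
            roles,
            [Role.WT_LYSATE.value, Role.BSA.value, Role.PROTEIN_A.value, Role.ANTIHUMAN.value],
        )
        levels[:] = cfg.poly_lysine_frac * base  # poly-L-lysine default
        levels[protein_like] = base
        levels[roles == Role.BUFFER.value] = cfg.buffer_protein_frac * base
        is_lysate = roles == Role.LYSATE.value
        levels[is_lysate] = base * np.array(
            [abundance.get(n, 1.0) for n in names[is_lysate]]
        )
    elif antibody == "antiHis":
        levels[:] = cfg.his_floor_frac * base
        is_lysate = roles == Role.LYSATE.value
        expressed = is_lysate & np.array([n in expressors for n in names])
        levels[expressed] = base * np.array(
            [abundance.get(n, 1.0) for n in names[expressed]]
        )
    else:  # anti-phosphotyrosine experiment channel
        levels[:] = floor
        is_lysate = roles == Role.LYSATE.value
        levels[is_lysate] = base
        levels[roles == Role.WT_LYSATE.value] = base
        for name in cfg.planted_kinases:
            effect = cfg.kinase_effect(name, antibody)
            if effect:
                levels[(names == name) & is_lysate] = base * (1.0 + effect * u)

    levels[roles == Role.LANDMARK.value] = cfg.landmark_level * base
    return levels


def _draw_scan(
    template: pd.DataFrame,
    levels: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    *,
    assay_id: str,
    antibody: str,
    condition: str,
    batch: str,
) -> ArrayScan:
    n = len(template)
    batch_factor = float(_lognormal(rng, cfg.batch_scale_sd, 1)[0])
    spot_noise = _lognormal(rng, cfg.spot_cv, n)
    if cfg.background_sd > 0:
        bg_true = np.clip(rng.normal(cfg.background_mean, cfg.background_sd, n), 0.0, None)
    else:
        bg_true = np.full(n, cfg.background_mean)
    foreground = np.rint(bg_true + batch_factor * levels * spot_noise)
    spots = template.assign(
        foreground=foreground,
        background=float(np.rint(cfg.background_mean)),
        flag=0,
    )
    return ArrayScan(
        spots, assay_id=assay_id, antibody=antibody, condition=condition, batch=batch
    )


def _clone_params(cfg: SimConfig, names: Sequence[str], rng: np.random.Generator):
    abundance_draws = _lognormal(rng, cfg.abundance_cv, len(names))
    abundance = dict(zip(names, abundance_draws))
    k = int(round(cfg.his_positive_fraction * len(names)))
    order = rng.permutation(len(names))
    expressors = frozenset(names[i] for i in order[:k])
    return abundance, expressors


def simulate_ecla(config: SimConfig) -> SimResult:
    """Simulate the lysate-array screen: per antibody, ``n_replicate_assays``
    experiment scans and as many secondary-only blanks, plus (optionally)
    total-protein and anti-His QC scans in ``n_qc_batches`` batches.
    """
    config.validate()
    names = config.resolve_names("clone")
    layout = _build_sim_layout(config, names)
    template = _template_frame(layout)

    plan: list[tuple[str, str, str]] = []  # (antibody, condition, batch label)
    for antibody in config.antibodies:
        for condition in ("experiment", "control_no_primary"):
            for rep in range(1, config.n_replicate_assays + 1):
                plan.append((antibody, condition, f"rep{rep}"))
    if config.include_qc_channels:
        for antibody in ("NHS_ester", "antiHis"):
            for b in range(1, config.n_qc_batches + 1):
                plan.append((antibody, "experiment", f"batch{b}"))

    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(len(plan) + 1)
    abundance, expressors = _clone_params(
        config, names, np.random.default_rng(children[0])
    )

    scans = []
    level_cache: dict[tuple[str, str], np.ndarray] = {}
    for child, (antibody, condition, batch) in zip(children[1:], plan):
        key = (antibody, condition)
        if key not in level_cache:
            level_cache[key] = _expected_levels(
                template, antibody, condition, config, abundance, expressors
            )
        scans.append(
            _draw_scan(
                template,
                level_cache[key],
                config,
                np.random.default_rng(child),
                assay_id=f"{antibody}_{condition}_{batch}",
                antibody=antibody,
                condition=condition,
                batch=batch,
            )
        )

    truth_rows = [
        (clone, antibody, config.kinase_effect(clone, antibody))
        for clone in config.planted_kinases
        for antibody in config.antibodies
    ]
    truth_rows += [(clone, "antiHis", 1.0) for clone in sorted(expressors)]
    truth = pd.DataFrame(truth_rows, columns=["name", "channel", "effect"])
    return SimResult(scans=scans, layout=layout, truth=truth, config=config)


def simulate_proteome_array(config: SimConfig) -> SimResult:
    """Simulate the forward-phase purified-protein array: anti-pTyr scans of
    ``n_replicate_assays`` replicates per ±ATP condition; planted substrates
    receive their effect only in the ``plus_ATP`` scans.
    """
    config.validate()
    names = config.resolve_names("prot")
    layout = _build_sim_layout(config, names)
    template = _template_frame(layout)

    plan = [
        (condition, f"rep{rep}")
        for condition in ("plus_ATP", "minus_ATP")
        for rep in range(1, config.n_replicate_assays + 1)
    ]
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(len(plan) + 1)
    abundance, expressors = _clone_params(
        config, names, np.random.default_rng(children[0])
    )

    scans = []
    level_cache: dict[str, np.ndarray] = {}
    for child, (condition, batch) in zip(children[1:], plan):
        if condition not in level_cache:
            level_cache[condition] = _expected_levels(
                template, "pTyr100", condition, config, abundance, expressors,
                proteome=True,
            )
        scans.append(
            _draw_scan(
                template,
                level_cache[condition],
                config,
                np.random.default_rng(child),
                assay_id=f"pTyr100_{condition}_{batch}",
                antibody="pTyr100",
                condition=condition,
                batch=batch,
            )
        )

    truth = pd.DataFrame(
        [(name, "plus_ATP", float(e)) for name, e in config.planted_substrates.items()],
        columns=["name", "channel", "effect"],
    )
    return SimResult(scans=scans, layout=layout, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Planted-truth recovery experiments mirroring the published screen's counts
# ---------------------------------------------------------------------------

def screen_recovery_config(seed: int = 0, n_clones: int = 4126) -> SimConfig:
    """Two-antibody lysate screen with 32 P-Tyr-100 / 7 PY20 positives planted,
    6 of them (the named candidates) as strong dual-antibody positives.
    Effects are in WT-SD units, all comfortably above the 1.5-SD gate.
    """
    dual = {"etk": 12.0, "wzc": 10.0, "nrdD": 8.0, "yjjJ": 7.0, "argG": 6.0, "dgoD": 5.0}
    planted: dict[str, dict[str, float]] = {
        clone: {"pTyr100": e, "PY20": 0.9 * e} for clone, e in dual.items()
    }
    for i, e in enumerate(np.linspace(4.0, 9.0, 26)):
        planted[f"kinA{i + 1:02d}"] = {"pTyr100": round(float(e), 3)}
    planted["kinB01"] = {"PY20": 5.0}
    return SimConfig(n_clones=n_clones, planted_kinases=planted, seed=seed)


def substrate_recovery_config(seed: int = 0, n_proteins: int = 4126) -> SimConfig:
    """Forward-phase ±ATP experiment with 33 large-effect substrates planted
    (ssuD strongest, then the exopolysaccharide-associated wcaC, fcl, kpsE),
    duplicate assays per condition.
    """
    planted: dict[str, float] = {"ssuD": 50.0, "wcaC": 30.0, "fcl": 28.0, "kpsE": 26.0}
    for i, e in enumerate(np.linspace(8.0, 24.0, 29)):
        planted[f"sub{i + 5:02d}"] = round(float(e), 3)
    return SimConfig(
        n_clones=n_proteins,
        planted_substrates=planted,
        antibodies=("pTyr100",),
        n_replicate_assays=2,
        include_qc_channels=False,
        seed=seed,
    )
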