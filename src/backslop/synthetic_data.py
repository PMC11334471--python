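"""Simulator of serially propagated milk-fermenting communities.

The generator emulates the study design the analysis pipeline expects:
26 lineages, each fermented six times (F1 for 24 h from a raw-milk-like
inoculum, then five 1:100 transfers into fresh milk fermented 18 h), with
pH logged every 5 min and a composition profile taken at the end of each
step plus a raw-milk (T0) profile.

Growth model (explicit stand-in, not a chemical claim): each species i with
biomass Bᵢ grows logistically with a linear pH-inhibition factor,

    dBᵢ/dt = r_maxᵢ · gᵢ(pH) · Bᵢ · (1 − ΣB/K),   t ≥ lagᵢ,
    gᵢ(pH) = max(0, (pH − ph_minᵢ) / (ph0 − ph_minᵢ)),

and acidification is driven directly by growth,

    dpH/dt = −Σᵢ acid_yieldᵢ · (dBᵢ/dt)₊,   clamped at ph_floor.

This is the simplest mechanism producing lag → drop → plateau pH curves and
acid-tolerance-driven succession: a fast acidifier with a higher pH floor
(Lactococcus-like) stalls first, leaving late growth — and hence gradual
enrichment across transfers — to a slower-starting, more acid-tolerant,
higher-yield species (Lactobacillus-like).  Two between-step mechanisms
shape lineage dynamics on top of the within-step model: a small per-step
"batch effect" on growth rates (day-to-day process variability), and an
acid-stress carry-over in which cells harvested below their own pH floor
start the next fermentation with a longer lag, scaled by a per-species
stress sensitivity (low for lactobacilli and enterobacteria, which carry
dedicated acid-resistance systems; high for lactococci).

Three lineage archetypes are generated (mirroring stable single-dominant,
moderately drifting multi-LAB, and Lactococcus→Lactobacillus successional
dynamics), mixed 5:9:12 over 26 lineages by default.  Observation noise is
added to the emitted pH only; composition tables are emitted noise-free
(optionally multinomially resampled), and noiseless ground-truth kinetics
and Bray–Curtis values are recorded for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .community_metrics import bray_curtis
from .io_formats import CommunityProfile, PHTimeCourse, PipelineConfig

__all__ = [
    "SpeciesTrait",
    "SimConfig",
    "SyntheticStep",
    "SyntheticLineage",
    "Cohort",
    "trait_archetype",
    "simulate_fermentation",
    "dilute",
    "apply_extinction",
    "serial_propagate",
    "generate_cohort",
    "write_cohort",
]

ARCHETYPES = ("stable", "drifting", "successional")

_PHYLUM = {
    "Lactococcus": "Bacillota",
    "Streptococcus": "Bacillota",
    "Lactobacillus": "Bacillota",
    "Enterococcus": "Bacillota",
    "Leuconostoc": "Bacillota",
    "Staphylococcus": "Bacillota",
    "Bacillus": "Bacillota",
    "Escherichia": "Pseudomonadota",
    "Klebsiella": "Pseudomonadota",
    "Enterobacter": "Pseudomonadota",
    "Serratia": "Pseudomonadota",
    "Pseudomonas": "Pseudomonadota",
    "Acinetobacter": "Pseudomonadota",
    "Chryseobacterium": "Bacteroidota",
    "Flavobacterium": "Bacteroidota",
    "Corynebacterium": "Actinomycetota",
    "Rothia": "Actinomycetota",
    "Kocuria": "Actinomycetota",
    "Micrococcus": "Actinomycetota",
    "Brevibacterium": "Actinomycetota",
}

_LAB_GENERA = {"Lactococcus", "Streptococcus", "Lactobacillus", "Enterococcus",
               "Leuconostoc"}


@dataclass(frozen=True)
class SpeciesTrait:
    """Growth/acidification parameters of one simulated species (= one ASV)."""

    name: str
    genus: str
    phylum: str
    r_max: float  # 1/h
    ph_min: float  # growth floor, pH units
    acid_yield: float  # pH drop per unit biomass grown
    lag_h: float
    is_lab: bool
    stress_sens: float = 1.0  # acid-stress sensitivity (extra-lag multiplier)

    def __post_init__(self) -> None:
        if not 0 < self.r_max <= 3:
            raise ValueError("r_max must be in (0, 3]")
        if self.ph_min >= 6.7:
            raise ValueError("ph_min must lie below the initial milk pH (6.7)")
        if self.acid_yield < 0 or self.lag_h < 0:
            raise ValueError("acid_yield and lag_h must be non-negative")


@dataclass
class SimConfig:
    """Experimental-design and integration parameters of the simulator."""

    n_lineages: int = 26
    n_steps: int = 6
    dilution: float = 0.01
    duration_first_h: float = 24.0
    duration_later_h: float = 18.0
    dt_h: float = 1.0 / 60.0
    sample_every_h: float = 1.0 / 12.0  # one pH reading per 5 min
    ph0: float = 6.7
    ph_floor: float = 3.8
    carrying_capacity: float = 2.2
    initial_biomass_f1: float = 1e-6  # raw milk load, fraction-of-K scale
    extinction_threshold: float = 1e-6
    noise_sd_ph: float = 0.01
    step_rate_sd: float = 0.05  # per-step batch effect on growth rates (log scale)
    acid_stress_lag_h_per_ph: float = 6.0  # extra lag per pH unit of acid stress
    pseudocount_scale: float = 1e5
    multinomial_depth: int | None = None  # sequencing-like resampling if set
    stochastic_bottleneck: bool = False
    bottleneck_cells: int = 10**6
    archetype_mix: tuple[float, float, float] = (5 / 26, 9 / 26, 12 / 26)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dilution < 1:
            raise ValueError("dilution must be in (0, 1)")
        if self.dt_h > self.sample_every_h:
            raise ValueError("dt_h must not exceed sample_every_h")
        if abs(sum(self.archetype_mix) - 1) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")


@dataclass
class SyntheticStep:
    step: str
    curve: PHTimeCourse  # observed (noisy) pH
    clean_ph: np.ndarray  # noiseless pH at the same timestamps
    profile: CommunityProfile
    rel_abundance: pd.Series  # noise-free composition
    true_params: kinetics.AcidificationParams


@dataclass
class SyntheticLineage:
    lineage_id: str
    archetype: str
    traits: list[SpeciesTrait]
    t0_profile: CommunityProfile
    steps: dict[str, SyntheticStep] = field(default_factory=dict)
    true_bc_adjacent: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class Cohort:
    lineages: list[SyntheticLineage]
    config: SimConfig
    manifest: dict


# ---------------------------------------------------------------------------
# trait archetypes
# ---------------------------------------------------------------------------

# Trait templates.  Rates, yields and floors are balanced so that a
# LAB-dominated fermentation plateaus near the dominant species' ph_min a
# few hours after drop onset, transfers regrow in ~2-3 h, and the
# acid-tolerant higher-yield Lactobacillus-like species gains share through
# the post-stall window plus acid-stress carry-over at each transfer.
_TEMPLATES: dict[str, dict] = {
    "lactococcus": dict(genus="Lactococcus", r_max=1.55, ph_min=4.60,
                        acid_yield=2.4, lag_h=1.2, is_lab=True, stress_sens=1.0),
    "streptococcus": dict(genus="Streptococcus", r_max=1.50, ph_min=4.50,
                          acid_yield=2.3, lag_h=1.4, is_lab=True, stress_sens=1.0),
    "lactobacillus": dict(genus="Lactobacillus", r_max=1.50, ph_min=4.15,
                          acid_yield=2.8, lag_h=1.8, is_lab=True, stress_sens=0.15),
    "lactobacillus_mild": dict(genus="Lactobacillus", r_max=1.42, ph_min=4.25,
                               acid_yield=2.6, lag_h=1.8, is_lab=True, stress_sens=0.3),
    "enterococcus": dict(genus="Enterococcus", r_max=1.38, ph_min=4.70,
                         acid_yield=2.0, lag_h=1.5, is_lab=True, stress_sens=0.8),
    "leuconostoc": dict(genus="Leuconostoc", r_max=1.00, ph_min=4.80,
                        acid_yield=1.6, lag_h=1.8, is_lab=True, stress_sens=1.0),
    "escherichia": dict(genus="Escherichia", r_max=1.60, ph_min=4.90,
                        acid_yield=0.3, lag_h=1.2, is_lab=False, stress_sens=0.25),
    "klebsiella": dict(genus="Klebsiella", r_max=1.55, ph_min=5.00,
                       acid_yield=0.3, lag_h=1.3, is_lab=False, stress_sens=0.25),
    "pseudomonas": dict(genus="Pseudomonas", r_max=0.50, ph_min=5.60,
                        acid_yield=0.0, lag_h=2.0, is_lab=False, stress_sens=1.0),
}


def _make_trait(template: str, rng: np.random.Generator) -> SpeciesTrait:
    base = _TEMPLATES[template]
    return SpeciesTrait(
        name=f"asv_{template}",
        genus=base["genus"],
        phylum=_PHYLUM[base["genus"]],
        r_max=float(np.clip(base["r_max"] * np.exp(rng.normal(0, 0.04)), 0.05, 3.0)),
        ph_min=float(np.clip(base["ph_min"] + rng.normal(0, 0.03), 3.0, 6.5)),
        acid_yield=float(base["acid_yield"] * np.exp(rng.normal(0, 0.04))),
        lag_h=float(base["lag_h"] * np.exp(rng.normal(0, 0.08))),
        is_lab=base["is_lab"],
        stress_sens=float(base.get("stress_sens", 1.0)),
    )


def trait_archetype(
    kind: str, seed_or_rng: int | np.random.Generator
) -> tuple[list[SpeciesTrait], np.ndarray]:
    """Species trait table and initial (F1 inoculum) shares for an archetype.

    * ``stable`` — one fast LAB at high initial share (>= 0.7) over a weak
      background: the lineage locks onto its dominant quickly.
    * ``drifting`` — 3-4 LAB of comparable fitness at comparable shares:
      shares shift gradually without a clean takeover.
    * ``successional`` — a Lactococcus-like fast acidifier dominant at start
      and a rarer Lactobacillus-like species with a pH floor >= 0.3 lower
      and a higher acid yield, plus Pseudomonadota background: the tolerant
      species overtakes across transfers.

    Traits are jittered per seed; the same seed gives identical tables.
    """
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if kind == "stable":
        dom = "lactococcus" if rng.random() < 0.6 else "streptococcus"
        minor = "streptococcus" if dom == "lactococcus" else "lactococcus"
        names = [dom, minor, "leuconostoc", "escherichia", "pseudomonas"]
        ec0 = rng.uniform(0.04, 0.12)
        rest = 0.20 - ec0 / 2  # keep the dominant share at >= 0.75 after scaling
        shares = np.array([0.80, rest * 0.4, rest * 0.25, ec0, rest * 0.35])
        traits = [_make_trait(n, rng) for n in names]
        # the minor LAB tracks the dominant at slightly lower fitness, so it
        # persists (small but nonzero adjacent dissimilarity) without winning
        traits[1] = dataclasses.replace(
            traits[1],
            r_max=float(traits[0].r_max * 0.93 * np.exp(rng.normal(0, 0.02))),
            ph_min=traits[0].ph_min + 0.05,
        )
        # a stable lineage's enterobacteria are slower than its starter LAB
        traits[3] = dataclasses.replace(
            traits[3], r_max=float(1.36 * np.exp(rng.normal(0, 0.04))))
        return traits, shares / shares.sum()
    elif kind == "drifting":
        names = ["lactococcus", "streptococcus", "enterococcus",
                 "lactobacillus_mild", "pseudomonas"]
        core = rng.dirichlet(np.full(4, 12.0)) * 0.95
        shares = np.concatenate([core, [0.05]])
        # comparable fitness: pull the four LAB onto common growth rates,
        # lags and acid floors so no species holds a structural advantage
        traits = [_make_trait(n, rng) for n in names]
        for i in range(4):
            traits[i] = dataclasses.replace(
                traits[i],
                r_max=float(1.48 * np.exp(rng.normal(0, 0.03))),
                lag_h=float(1.5 * np.exp(rng.normal(0, 0.08))),
                ph_min=float(4.45 + rng.normal(0, 0.08)),
            )
        return traits, shares / shares.sum()
    elif kind == "successional":
        names = ["lactococcus", "lactobacillus", "escherichia", "pseudomonas"]
        lb0 = rng.uniform(0.012, 0.025)
        ec0 = rng.uniform(0.08, 0.30)
        shares = np.array([0.78 - lb0, lb0, ec0, 0.06])
        traits = [_make_trait(n, rng) for n in names]
        # couple the two LAB so the takeover speed varies moderately: the
        # Lactobacillus-like species is slightly slower and starts later but
        # keeps a pH-tolerance window the Lactococcus-like one cannot use
        traits[1] = dataclasses.replace(
            traits[1],
            r_max=float(traits[0].r_max * 0.97 * np.exp(rng.normal(0, 0.015))),
            lag_h=float(2.0 * np.exp(rng.normal(0, 0.05))),
        )
        # enterobacteria fast but not faster than the starter Lactococcus
        traits[2] = dataclasses.replace(
            traits[2], r_max=float(1.48 * np.exp(rng.normal(0, 0.04))))
        return traits, shares / shares.sum()
    else:
        raise ValueError(f"unknown archetype {kind!r}")
    traits = [_make_trait(n, rng) for n in names]
    shares = shares / shares.sum()
    return traits, shares


# ---------------------------------------------------------------------------
# fermentation dynamics
# ---------------------------------------------------------------------------


def simulate_fermentation(
    abundances: np.ndarray,
    traits: Sequence[SpeciesTrait],
    duration_h: float,
    config: SimConfig,
    rate_factors: np.ndarray | None = None,
    lag_override: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate one fermentation step (explicit Euler, noiseless).

    Returns ``(times_h, ph, final_biomass)`` with pH sampled every
    ``sample_every_h`` (5 min by default) including t = 0.  Biomass stays
    non-negative and the pH is non-increasing, bounded in
    [ph_floor, ph0].  ``rate_factors`` scales each species' r_max for this
    step (batch effects); ``lag_override`` replaces the trait lags (used for
    acid-stress carry-over between steps).
    """
    b = np.asarray(abundances, dtype=float).copy()
    if np.any(b < 0):
        raise ValueError("negative input abundance")
    if b.sum() <= 0:
        raise ValueError("community extinct: no biomass to inoculate")
    if len(b) != len(traits):
        raise ValueError("abundances and traits length mismatch")

    r = np.array([t.r_max for t in traits])
    if rate_factors is not None:
        r = r * np.asarray(rate_factors, dtype=float)
    ph_min = np.array([t.ph_min for t in traits])
    yld = np.array([t.acid_yield for t in traits])
    lag = (np.asarray(lag_override, dtype=float) if lag_override is not None
           else np.array([t.lag_h for t in traits]))

    dt = config.dt_h
    stride = int(round(config.sample_every_h / dt))
    n_iter = int(round(duration_h / dt))
    K = config.carrying_capacity
    ph0 = config.ph0

    ph = ph0
    times = [0.0]
    phs = [ph]
    for i in range(n_iter):
        t = i * dt
        g = np.clip((ph - ph_min) / (ph0 - ph_min), 0.0, None)
        db = r * g * b * (t >= lag) * (1.0 - b.sum() / K)
        b = np.maximum(b + dt * db, 0.0)
        ph = max(ph - dt * float(np.sum(yld * np.maximum(db, 0.0))), config.ph_floor)
        if (i + 1) % stride == 0:
            times.append((i + 1) * dt)
            phs.append(ph)
    return np.asarray(times), np.asarray(phs), b


def dilute(final_biomass: np.ndarray, config: SimConfig) -> np.ndarray:
    """1:100-style transfer: pure scalar scaling, shares preserved exactly."""
    return np.asarray(final_biomass, dtype=float) * config.dilution


def apply_extinction(
    biomass: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Drop species lost in the transfer bottleneck.

    Deterministic default: any species below ``extinction_threshold``
    relative abundance is zeroed.  With ``stochastic_bottleneck`` the
    transferred community is resampled as ``bottleneck_cells`` cells drawn
    multinomially from the pre-transfer composition.
    """
    b = np.asarray(biomass, dtype=float).copy()
    total = b.sum()
    if total <= 0:
        raise ValueError("community extinct at transfer")
    if config.stochastic_bottleneck:
        if rng is None:
            raise ValueError("stochastic bottleneck requires an rng")
        cells = rng.multinomial(config.bottleneck_cells, b / total)
        return cells / config.bottleneck_cells * total
    b[b / total < config.extinction_threshold] = 0.0
    return b


def _profile_from_rel(
    sample_id: str,
    rel: pd.Series,
    taxonomy: Mapping[str, tuple[str, str, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> CommunityProfile:
    if config.multinomial_depth:
        counts = rng.multinomial(config.multinomial_depth, rel.to_numpy())
    else:
        counts = np.rint(rel.to_numpy() * config.pseudocount_scale)
    keep = counts > 0
    return CommunityProfile(
        sample_id=sample_id,
        counts={a: float(c) for a, c in zip(rel.index[keep], counts[keep])},
        taxonomy={a: taxonomy[a] for a in rel.index[keep]},
    )


def _taxonomy_of(traits: Sequence[SpeciesTrait]) -> dict[str, tuple[str, str, str]]:
    return {t.name: (t.phylum, t.genus, f"{t.genus} sp.") for t in traits}


_BG_GENERA = (
    "Pseudomonas", "Acinetobacter", "Chryseobacterium", "Flavobacterium",
    "Corynebacterium", "Rothia", "Kocuria", "Micrococcus", "Brevibacterium",
    "Staphylococcus", "Bacillus", "Serratia", "Enterobacter",
)


def make_background_pool(n_asvs: int = 120, seed: int = 0) -> dict[str, tuple[str, str, str]]:
    """Shared pool of raw-milk background ASVs (taxonomy only)."""
    rng = np.random.default_rng(seed)
    pool: dict[str, tuple[str, str, str]] = {}
    for i in range(n_asvs):
        genus = str(rng.choice(_BG_GENERA))
        pool[f"asv_bg_{i:03d}"] = (_PHYLUM[genus], genus, f"{genus} sp.")
    return pool


def _t0_profile(
    lineage_id: str,
    traits: Sequence[SpeciesTrait],
    init_shares: np.ndarray,
    bg_pool: Mapping[str, tuple[str, str, str]],
    config: SimConfig,
    rng: np.random.Generator,
) -> CommunityProfile:
    """Raw-milk-like profile: Pseudomonas-dominated, high richness, with the
    lineage's fermenting species present at low abundance."""
    bg_ids = list(bg_pool)
    n_bg = int(rng.integers(55, 75))
    chosen = rng.choice(len(bg_ids), size=n_bg, replace=False)
    pseudo_ids = [bg_ids[i] for i in chosen if bg_pool[bg_ids[i]][1] == "Pseudomonas"]
    other_ids = [bg_ids[i] for i in chosen if bg_pool[bg_ids[i]][1] != "Pseudomonas"]
    if not pseudo_ids:  # ensure the dominant genus is represented
        pseudo_ids = [i for i in bg_ids if bg_pool[i][1] == "Pseudomonas"][:3]

    dom_share = rng.uniform(0.50, 0.70)
    starter_share = 0.02  # the future fermenters are rare in raw milk
    rest = 1.0 - dom_share - starter_share

    rel: dict[str, float] = {}
    w = rng.dirichlet(np.full(len(pseudo_ids), 1.0)) * dom_share
    rel.update(dict(zip(pseudo_ids, w)))
    if other_ids:
        w = rng.dirichlet(np.full(len(other_ids), 0.4)) * rest
        rel.update({k: rel.get(k, 0.0) + v for k, v in zip(other_ids, w)})
    w = init_shares / init_shares.sum() * starter_share
    for t, v in zip(traits, w):
        rel[t.name] = rel.get(t.name, 0.0) + float(v)

    series = pd.Series(rel)
    series /= series.sum()
    taxonomy = dict(bg_pool)
    taxonomy.update(_taxonomy_of(traits))
    return _profile_from_rel(f"{lineage_id}_T0", series, taxonomy, config, rng)


def serial_propagate(
    initial_shares: np.ndarray,
    traits: Sequence[SpeciesTrait],
    config: SimConfig,
    rng: np.random.Generator,
    lineage_id: str = "L1",
    archetype: str = "custom",
    bg_pool: Mapping[str, tuple[str, str, str]] | None = None,
) -> SyntheticLineage:
    """Run the full serial-propagation scheme for one lineage.

    Step F1 runs ``duration_first_h`` from a dilute raw-milk-like inoculum;
    each later step starts from ``dilution`` x the previous final biomass
    (shares preserved exactly, then bottleneck extinction applied) and runs
    ``duration_later_h``.  Emits per-step noisy pH curves, pseudo-count
    profiles, noiseless ground-truth kinetics and adjacent-step Bray–Curtis.
    """
    taxonomy = _taxonomy_of(traits)
    shares = np.asarray(initial_shares, dtype=float)
    b = shares / shares.sum() * config.initial_biomass_f1
    names = pd.Index([t.name for t in traits])

    bg_pool = bg_pool if bg_pool is not None else make_background_pool(seed=config.seed)
    lineage = SyntheticLineage(
        lineage_id=lineage_id,
        archetype=archetype,
        traits=list(traits),
        t0_profile=_t0_profile(lineage_id, traits, shares, bg_pool, config, rng),
    )

    rels: list[tuple[str, pd.Series]] = []
    prev_final_ph: float | None = None
    for k in range(1, config.n_steps + 1):
        step = f"F{k}"
        duration = config.duration_first_h if k == 1 else config.duration_later_h
        # per-step batch effect: small day-to-day variability of growth rates
        factors = np.exp(rng.normal(0.0, config.step_rate_sd, len(traits)))
        # acid-stress carry-over: cells harvested below their own pH floor
        # start the next fermentation with a proportionally longer lag
        base_lag = np.array([t.lag_h for t in traits])
        ph_min = np.array([t.ph_min for t in traits])
        if prev_final_ph is None:
            lag_eff = base_lag
        else:
            stress = np.maximum(0.0, ph_min - prev_final_ph)
            sens = np.array([t.stress_sens for t in traits])
            lag_eff = base_lag + config.acid_stress_lag_h_per_ph * sens * stress
        times, ph_clean, b_final = simulate_fermentation(
            b, traits, duration, config,
            rate_factors=factors, lag_override=lag_eff,
        )
        prev_final_ph = float(ph_clean[-1])
        noisy = np.clip(ph_clean + rng.normal(0.0, config.noise_sd_ph, ph_clean.shape),
                        0.0, 14.0)
        curve = PHTimeCourse(lineage_id, step, times, noisy)
        clean_curve = PHTimeCourse(lineage_id, step, times, ph_clean)
        true_params = kinetics.extract_params(
            clean_curve, PipelineConfig(), horizon_h=duration
        )
        rel = pd.Series(b_final, index=names)
        rel /= rel.sum()
        profile = _profile_from_rel(f"{lineage_id}_{step}", rel, taxonomy, config, rng)
        lineage.steps[step] = SyntheticStep(
            step=step,
            curve=curve,
            clean_ph=ph_clean,
            profile=profile,
            rel_abundance=rel,
            true_params=true_params,
        )
        rels.append((step, rel))
        if k < config.n_steps:
            b = apply_extinction(dilute(b_final, config), config,
                                 rng if config.stochastic_bottleneck else None)
            if b.sum() <= 0:
                raise RuntimeError(f"community extinct at transfer after {step}")

    for (sa, ra), (sb, rb) in zip(rels[1:], rels[2:]):  # F2-F3 ... F5-F6
        lineage.true_bc_adjacent.append((f"{sa}-{sb}", bray_curtis(ra, rb)))
    return lineage


def _archetype_counts(mix: Sequence[float], n: int) -> list[int]:
    raw = np.asarray(mix, dtype=float) * n
    counts = np.floor(raw).astype(int)
    # hand the remainder to the largest fractional parts, deterministically
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def generate_cohort(config: SimConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort (lineages + manifest).

    Archetypes are assigned in fixed proportions (default 5:9:12 stable /
    drifting / successional over 26 lineages); every source of randomness
    derives from ``config.seed`` via spawned child generators, so the same
    seed reproduces the cohort exactly.
    """
    config = config or SimConfig()
    counts = _archetype_counts(config.archetype_mix, config.n_lineages)
    archetypes = [a for a, c in zip(ARCHETYPES, counts) for _ in range(c)]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_lineages + 1)
    bg_pool = make_background_pool(seed=config.seed)

    lineages = []
    for i, archetype in enumerate(archetypes):
        rng = np.random.default_rng(children[i])
        traits, shares = trait_archetype(archetype, rng)
        lineages.append(
            serial_propagate(
                shares, traits, config, rng,
                lineage_id=f"M{i + 1}", archetype=archetype, bg_pool=bg_pool,
            )
        )
    manifest = {
        "seed": config.seed,
        "archetype_counts": dict(zip(ARCHETYPES, counts)),
        "archetypes": {lin.lineage_id: lin.archetype for lin in lineages},
    }
    return Cohort(lineages=lineages, config=config, manifest=manifest)


# ---------------------------------------------------------------------------
# file emission (io_formats-compatible)
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the plain-text file set the readers consume.

    ``ph_logs/<lineage>_<step>.csv`` (time_min + one pH channel),
    ``abundance.tsv`` (samples x ASVs pseudo-counts), ``taxonomy.tsv``,
    ``metadata.tsv`` and ``ground_truth.json``.
    """
    out = Path(out_dir)
    (out / "ph_logs").mkdir(parents=True, exist_ok=True)

    meta_rows = []
    profiles: dict[str, CommunityProfile] = {}
    taxonomy: dict[str, tuple[str, str, str]] = {}
    gt: dict = {"archetypes": cohort.manifest["archetypes"], "lineages": {}}

    for lin in cohort.lineages:
        profiles[lin.t0_profile.sample_id] = lin.t0_profile
        taxonomy.update(lin.t0_profile.taxonomy)
        meta_rows.append((lin.t0_profile.sample_id, lin.lineage_id, "T0"))
        gl: dict = {"archetype": lin.archetype, "steps": {}, "bc_adjacent": {}}
        for step, srec in lin.steps.items():
            sample_id = f"{lin.lineage_id}_{step}"
            profiles[sample_id] = srec.profile
            taxonomy.update(srec.profile.taxonomy)
            meta_rows.append((sample_id, lin.lineage_id, step))
            pd.DataFrame(
                {"time_min": srec.curve.times * 60.0, sample_id: srec.curve.ph}
            ).to_csv(out / "ph_logs" / f"{sample_id}.csv", index=False)
            tp = srec.true_params
            gl["steps"][step] = {
                "lag_h": tp.lag_h,
                "mar": tp.mar,
                "final_ph": tp.final_ph,
            }
        gl["bc_adjacent"] = dict(lin.true_bc_adjacent)
        gt["lineages"][lin.lineage_id] = gl

    all_asvs = sorted(taxonomy)
    table = pd.DataFrame(
        0.0, index=sorted(profiles), columns=all_asvs
    )
    for sid, prof in profiles.items():
        for asv, c in prof.counts.items():
            table.at[sid, asv] = c
    table.index.name = "sample_id"
    table.astype(int).to_csv(out / "abundance.tsv", sep="\t")

    tax_df = pd.DataFrame(
        [(a, *taxonomy[a]) for a in all_asvs],
        columns=["asv_id", "phylum", "genus", "species"],
    )
    tax_df.to_csv(out / "taxonomy.tsv", sep="\t", index=False)

    pd.DataFrame(meta_rows, columns=["sample_id", "lineage_id", "step"]).to_csv(
        out / "metadata.tsv", sep="\t", index=False
    )
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(cohort.config), **gt},
            fh, indent=2, sort_keys=True,
        )
    return {
        "abundance": out / "abundance.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "ground_truth": out / "ground_truth.json",
        "ph_logs": out / "ph_logs",
    }
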