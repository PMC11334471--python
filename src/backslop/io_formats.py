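"""File formats, domain containers and lineage assembly.

The artifact consumes three kinds of plain-text inputs:

* pH-logger time courses (CSV/TSV; one time column plus one pH column per
  logger channel, channels mapped to (lineage, step) via sample metadata),
* an ASV abundance table (samples x ASVs, counts) with a taxonomy table
  (ASV -> phylum/genus/species),
* a metadata table mapping sample ids to lineage x propagation step.

All times are carried internally in hours; minute-based logger files are
converted on read.  Steps are T0 (raw milk, no pH curve) and F1..F6 (six
serial fermentations; F1 runs 24 h, F2..F6 run 18 h).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

STEP_ORDER: tuple[str, ...] = ("T0", "F1", "F2", "F3", "F4", "F5", "F6")
FERMENTED_STEPS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6")
#: Steps entering adjacent-pair (beta-diversity / delta) series.
DYNAMICS_STEPS: tuple[str, ...] = ("F2", "F3", "F4", "F5", "F6")

#: Lactic acid bacteria genera (Lactobacillales) used for the LAB fraction.
DEFAULT_LAB_GENERA: frozenset[str] = frozenset(
    {
        "Enterococcus",
        "Lactobacillus",  # sensu lato; see LACTOBACILLUS_SENSU_LATO_ALIASES
        "Lactococcus",
        "Leuconostoc",
        "Oenococcus",
        "Pediococcus",
        "Streptococcus",
        "Weissella",
    }
)

#: Genera of the 2020 split of the former broad genus *Lactobacillus*.
#: Any of these is treated as "Lactobacillus sensu lato".
LACTOBACILLUS_SENSU_LATO_ALIASES: frozenset[str] = frozenset(
    {
        "Lactobacillus",
        "Lacticaseibacillus",
        "Lactiplantibacillus",
        "Limosilactobacillus",
        "Levilactobacillus",
        "Lentilactobacillus",
        "Ligilactobacillus",
        "Latilactobacillus",
        "Loigolactobacillus",
        "Liquorilactobacillus",
        "Secundilactobacillus",
        "Companilactobacillus",
        "Fructilactobacillus",
        "Paucilactobacillus",
        "Schleiferilactobacillus",
        "Apilactobacillus",
        "Bombilactobacillus",
        "Agrilactobacillus",
        "Acetilactobacillus",
        "Furfurilactobacillus",
        "Holzapfelia",
        "Amylolactobacillus",
        "Paralactobacillus",
        "Dellaglioa",
    }
)

DEFAULT_HORIZONS_H: dict[str, float] = {
    "F1": 24.0,
    "F2": 18.0,
    "F3": 18.0,
    "F4": 18.0,
    "F5": 18.0,
    "F6": 18.0,
}


class FormatError(ValueError):
    """Raised on malformed input files or inconsistent tables."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PHTimeCourse:
    """One fermentation step's pH trace.

    ``times`` are hours since inoculation, strictly increasing; ``ph`` has the
    same length and lies in [0, 14].  A curve is eligible for kinetics
    extraction only if it holds at least two full regression windows
    (``2 * window_points`` samples).
    """

    lineage_id: str
    step: str
    times: np.ndarray
    ph: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        ph = np.asarray(self.ph, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "ph", ph)
        if self.step not in FERMENTED_STEPS:
            raise ValueError(f"pH curves only exist for F1..F6, got {self.step!r}")
        if times.shape != ph.shape or times.ndim != 1:
            raise ValueError("times and ph must be 1-D arrays of equal length")
        if len(times) >= 2:
            diffs = np.diff(times)
            bad = np.flatnonzero(diffs <= 0)
            if bad.size:
                raise FormatError(
                    f"non-increasing time axis at row {bad[0] + 1} "
                    f"({self.lineage_id}/{self.step})"
                )
        if ph.size and (np.nanmin(ph) < 0.0 or np.nanmax(ph) > 14.0):
            raise FormatError(
                f"pH outside [0, 14] in {self.lineage_id}/{self.step}"
            )

    def __len__(self) -> int:
        return len(self.times)

    def is_eligible(self, window_points: int = 20) -> bool:
        return len(self) >= 2 * window_points


@dataclass(frozen=True)
class CommunityProfile:
    """One sample's ASV counts plus taxonomy lookup.

    ``counts`` maps ASV id to a non-negative (possibly fractional) abundance;
    ``taxonomy`` maps every ASV in ``counts`` to a (phylum, genus, species)
    triple where any level may be ``"unassigned"``.
    """

    sample_id: str
    counts: Mapping[str, float]
    taxonomy: Mapping[str, tuple[str, str, str]]

    def __post_init__(self) -> None:
        for asv, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for {asv} in {self.sample_id}")
            if asv not in self.taxonomy:
                raise ValueError(f"ASV {asv} in counts lacks a taxonomy entry")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def as_series(self) -> pd.Series:
        return pd.Series(dict(self.counts), dtype=float, name=self.sample_id)

    def genus_of(self, asv: str) -> str:
        return self.taxonomy[asv][1]

    def phylum_of(self, asv: str) -> str:
        return self.taxonomy[asv][0]


@dataclass
class StepRecord:
    """A single step within a lineage (profile and/or curve may be missing)."""

    step: str
    profile: CommunityProfile | None = None
    curve: PHTimeCourse | None = None
    horizon_h: float | None = None


@dataclass
class Lineage:
    """One raw-milk sample and its serially fermented descendants (T0, F1..F6)."""

    lineage_id: str
    steps: dict[str, StepRecord] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def ordered_steps(self) -> list[StepRecord]:
        return [self.steps[s] for s in STEP_ORDER if s in self.steps]

    def profile_at(self, step: str) -> CommunityProfile | None:
        rec = self.steps.get(step)
        return rec.profile if rec else None

    def curve_at(self, step: str) -> PHTimeCourse | None:
        rec = self.steps.get(step)
        return rec.curve if rec else None

    def profiles_by_step(self, steps: Sequence[str] = DYNAMICS_STEPS) -> dict[str, CommunityProfile]:
        out: dict[str, CommunityProfile] = {}
        for s in steps:
            p = self.profile_at(s)
            if p is not None:
                out[s] = p
        return out

    def has_consecutive_profiles(self, steps: Sequence[str] = DYNAMICS_STEPS) -> bool:
        """True if >= 2 consecutive steps carry profiles (dynamics eligibility)."""
        present = [self.profile_at(s) is not None for s in steps]
        return any(a and b for a, b in zip(present, present[1:]))


@dataclass
class PipelineConfig:
    """Tunable analysis parameters with their field-standard defaults."""

    window_points: int = 20
    dilution: float = 0.01
    minor_genus_threshold: float = 0.05
    dominance_threshold: float = 0.5
    lab_genera: frozenset[str] = DEFAULT_LAB_GENERA
    lactobacillus_aliases: frozenset[str] = LACTOBACILLUS_SENSU_LATO_ALIASES
    horizons: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HORIZONS_H))
    nmds_dimensions: int = 2
    nmds_restarts: int = 32
    shannon_base: float | None = None  # None -> natural log (nats)
    stability_bc_low: float = 0.08
    stability_bc_high: float = 0.20
    breakpoint_grid_step: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_points < 2:
            raise ValueError("window_points must be >= 2")
        if not 0 < self.dilution < 1:
            raise ValueError("dilution must be in (0, 1)")
        for name in ("minor_genus_threshold", "dominance_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        self.lab_genera = frozenset(self.lab_genera)
        self.lactobacillus_aliases = frozenset(self.lactobacillus_aliases)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lab_genera"] = sorted(self.lab_genera)
        d["lactobacillus_aliases"] = sorted(self.lactobacillus_aliases)
        return d


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_ph_log(
    path: str | Path,
    mapping: Mapping[str, tuple[str, str]],
    time_unit: str | None = None,
) -> list[PHTimeCourse]:
    """Read a logger file into one :class:`PHTimeCourse` per mapped channel.

    The first column is time (minutes or hours); every other column is a pH
    channel.  The unit is taken from ``time_unit`` ("min"/"h") or inferred
    from the time column's header (a name containing "min" means minutes,
    otherwise hours).  Channels absent from ``mapping`` are skipped with a
    warning; a non-monotonic time column or out-of-range pH is a hard error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a time column plus >= 1 pH channel")
    time_col = df.columns[0]
    if time_unit is None:
        time_unit = "min" if "min" in str(time_col).lower() else "h"
    if time_unit not in {"min", "h"}:
        raise ValueError("time_unit must be 'min' or 'h'")
    t = df[time_col].to_numpy(dtype=float)
    diffs = np.diff(t)
    bad = np.flatnonzero(diffs <= 0)
    if bad.size:
        raise FormatError(
            f"{path}: non-monotonic time column at row {int(bad[0]) + 2} "
            f"(value {t[bad[0] + 1]!r} after {t[bad[0]]!r})"
        )
    times_h = t / 60.0 if time_unit == "min" else t

    curves: list[PHTimeCourse] = []
    for col in df.columns[1:]:
        if col not in mapping:
            logger.warning("channel %r in %s not mapped; skipped", col, path)
            continue
        ph = df[col].to_numpy(dtype=float)
        if np.nanmin(ph) < 0.0 or np.nanmax(ph) > 14.0:
            raise FormatError(f"{path}: pH outside [0, 14] in channel {col!r}")
        lineage_id, step = mapping[col]
        curves.append(PHTimeCourse(lineage_id, step, times_h.copy(), ph))
    return curves


def read_abundance(
    path_counts: str | Path,
    path_taxonomy: str | Path,
    orientation: str = "samples_x_asvs",
) -> list[CommunityProfile]:
    """Read counts + taxonomy tables into :class:`CommunityProfile` objects.

    ``orientation`` declares whether rows of the counts TSV are samples
    (``"samples_x_asvs"``) or ASVs (``"asvs_x_samples"``).  ASVs lacking a
    taxonomy row fall back to all-"unassigned" levels with a warning; samples
    with zero total count are excluded with a warning; duplicate sample ids
    are a hard error.
    """
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    if orientation == "asvs_x_samples":
        counts = counts.T
    elif orientation != "samples_x_asvs":
        raise ValueError("orientation must be 'samples_x_asvs' or 'asvs_x_samples'")
    if counts.index.duplicated().any():
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")

    tax = pd.read_csv(path_taxonomy, sep="\t", index_col=0)
    tax_map: dict[str, tuple[str, str, str]] = {}
    for asv, row in tax.iterrows():
        tax_map[str(asv)] = (
            str(row.get("phylum", "unassigned")),
            str(row.get("genus", "unassigned")),
            str(row.get("species", "unassigned")),
        )

    profiles: list[CommunityProfile] = []
    for sample_id, row in counts.iterrows():
        vals = row.astype(float)
        nonzero = vals[vals > 0]
        if nonzero.sum() <= 0:
            logger.warning("sample %s has zero total count; excluded", sample_id)
            continue
        taxonomy: dict[str, tuple[str, str, str]] = {}
        for asv in nonzero.index:
            asv = str(asv)
            if asv in tax_map:
                taxonomy[asv] = tax_map[asv]
            else:
                logger.warning("ASV %s missing from taxonomy; set to unassigned", asv)
                taxonomy[asv] = ("unassigned", "unassigned", "unassigned")
        profiles.append(
            CommunityProfile(
                sample_id=str(sample_id),
                counts={str(a): float(v) for a, v in nonzero.items()},
                taxonomy=taxonomy,
            )
        )
    return profiles


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample -> (lineage, step) mapping table."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "lineage_id", "step"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad_steps = set(meta["step"]) - set(STEP_ORDER)
    if bad_steps:
        raise FormatError(f"unknown steps in metadata: {sorted(bad_steps)}")
    return meta


def assemble_lineages(
    profiles: Iterable[CommunityProfile],
    curves: Iterable[PHTimeCourse],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> list[Lineage]:
    """Join profiles and curves into per-lineage step series.

    Missing steps are tolerated and recorded in ``Lineage.flags`` (their
    adjacent pairs simply drop out of downstream series); two samples mapped
    to the same (lineage, step) are a hard error.
    """
    config = config or PipelineConfig()
    sample_to_slot = {
        str(r.sample_id): (str(r.lineage_id), str(r.step))
        for r in metadata.itertuples()
    }
    lineages: dict[str, Lineage] = {}

    def slot(lineage_id: str, step: str) -> StepRecord:
        lin = lineages.setdefault(lineage_id, Lineage(lineage_id))
        if step not in lin.steps:
            lin.steps[step] = StepRecord(step=step, horizon_h=config.horizons.get(step))
        return lin.steps[step]

    for p in profiles:
        if p.sample_id not in sample_to_slot:
            logger.warning("profile %s not in metadata; skipped", p.sample_id)
            continue
        lid, step = sample_to_slot[p.sample_id]
        rec = slot(lid, step)
        if rec.profile is not None:
            raise FormatError(f"duplicate profile for ({lid}, {step})")
        rec.profile = p

    for c in curves:
        rec = slot(c.lineage_id, c.step)
        if rec.curve is not None:
            raise FormatError(f"duplicate pH curve for ({c.lineage_id}, {c.step})")
        rec.curve = c

    out = []
    for lid in sorted(lineages):
        lin = lineages[lid]
        missing = [s for s in STEP_ORDER if s not in lin.steps or
                   (s != "T0" and lin.steps[s].profile is None)]
        if missing:
            lin.flags.append(f"missing_steps:{','.join(missing)}")
        if not lin.has_consecutive_profiles():
            lin.flags.append("ineligible_for_dynamics")
        # order the step dict canonically
        lin.steps = {s: lin.steps[s] for s in STEP_ORDER if s in lin.steps}
        out.append(lin)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    extra_metadata: Mapping | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a run-metadata JSON.

    Floats are written with pandas' repr-based default formatting, so a
    re-read reproduces every numeric column exactly; column order is the
    DataFrame's own and therefore stable for a fixed pipeline version.
    """
    from backslop import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on fs permissions
        raise FormatError(f"cannot create output directory {out_dir}: {exc}") from exc
    written: dict[str, Path] = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path
    meta = {
        "version": __version__,
        "seed": seed,
        "config": config.to_dict() if config is not None else None,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    meta_path = out_dir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    written["run_metadata"] = meta_path
    return written


def canonical_genus(genus: str, aliases: frozenset[str] = LACTOBACILLUS_SENSU_LATO_ALIASES) -> str:
    """Collapse post-2020 split genera onto 'Lactobacillus' (sensu lato)."""
    return "Lactobacillus" if genus in aliases else genus
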