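"""Alpha/beta diversity and composition summaries on per-step ASV profiles.

All metrics operate on relative abundances.  Shannon entropy defaults to
natural log (nats); Bray–Curtis dissimilarity is computed on the union of
the two samples' ASV sets (missing = 0), BC = Σ|pᵢ − qᵢ| / Σ(pᵢ + qᵢ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _scipy_braycurtis

from .io_formats import (
    DYNAMICS_STEPS,
    FERMENTED_STEPS,
    CommunityProfile,
    Lineage,
    PipelineConfig,
    canonical_genus,
)

__all__ = [
    "DynamicsSummary",
    "relative_abundance",
    "richness",
    "shannon",
    "bray_curtis",
    "adjacent_series",
    "aggregate_minor_genera",
    "lab_fraction",
    "dominant_taxon",
    "build_dynamics_summary",
    "bray_curtis_matrix",
]

DOMINANCE_CATEGORIES = (
    "Lactobacillus sensu lato",
    "Lactococcus",
    "Streptococcus",
    "other-LAB",
    "Pseudomonadota",
    "none",
)


def relative_abundance(profile: CommunityProfile | pd.Series) -> pd.Series:
    """Normalise counts to sum to one; zero entries are preserved."""
    s = profile.as_series() if isinstance(profile, CommunityProfile) else pd.Series(profile, dtype=float)
    total = float(s.sum())
    if total <= 0:
        raise ValueError("cannot normalise a profile with zero total count")
    return s / total


def richness(profile: CommunityProfile | pd.Series) -> int:
    """Observed richness: number of ASVs with abundance > 0 (no rarefaction)."""
    s = profile.as_series() if isinstance(profile, CommunityProfile) else pd.Series(profile, dtype=float)
    return int((s > 0).sum())


def shannon(profile: CommunityProfile | pd.Series, base: float | None = None) -> float:
    """Shannon entropy H = −Σ pᵢ log pᵢ over nonzero relative abundances.

    ``base=None`` means natural log (nats); pass e.g. ``base=2`` for bits.
    """
    p = relative_abundance(profile).to_numpy()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    # guard against -0.0 on single-taxon profiles
    return abs(h) if h == 0 else h


def _align_pair(p: CommunityProfile | pd.Series, q: CommunityProfile | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    ps = relative_abundance(p)
    qs = relative_abundance(q)
    union = ps.index.union(qs.index)
    return (
        ps.reindex(union, fill_value=0.0).to_numpy(),
        qs.reindex(union, fill_value=0.0).to_numpy(),
    )


def bray_curtis(p: CommunityProfile | pd.Series, q: CommunityProfile | pd.Series) -> float:
    """Bray–Curtis dissimilarity between two profiles on relative abundances.

    0 iff identical composition, 1 iff disjoint ASV supports.
    """
    pv, qv = _align_pair(p, q)
    return float(_scipy_braycurtis(pv, qv))


def bray_curtis_matrix(profiles: Sequence[CommunityProfile]) -> pd.DataFrame:
    """Square symmetric BC matrix over samples, aligned on the global ASV set."""
    table = pd.DataFrame(
        {p.sample_id: relative_abundance(p) for p in profiles}
    ).fillna(0.0).T
    arr = table.to_numpy()
    n = len(arr)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _scipy_braycurtis(arr[i], arr[j])
    return pd.DataFrame(d, index=table.index, columns=table.index)


def adjacent_series(
    profiles_by_step: Mapping[str, CommunityProfile],
    metric: str,
    steps: Sequence[str] = DYNAMICS_STEPS,
    shannon_base: float | None = None,
) -> tuple[list[tuple[str, float]], float]:
    """Per-adjacent-pair values of a metric along a lineage, plus their sum.

    ``metric`` is ``"braycurtis"`` (pairwise dissimilarity, summed as-is) or
    ``"shannon"`` / ``"richness"`` (absolute adjacent differences, so the sum
    is a fluctuation total).  Pairs with a missing member are omitted; with
    fewer than two usable steps the series is empty.
    """
    pairs: list[tuple[str, float]] = []
    for a, b in zip(steps, steps[1:]):
        pa, pb = profiles_by_step.get(a), profiles_by_step.get(b)
        if pa is None or pb is None:
            continue
        label = f"{a}-{b}"
        if metric == "braycurtis":
            pairs.append((label, bray_curtis(pa, pb)))
        elif metric == "shannon":
            pairs.append((label, abs(shannon(pb, shannon_base) - shannon(pa, shannon_base))))
        elif metric == "richness":
            pairs.append((label, float(abs(richness(pb) - richness(pa)))))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return pairs, float(sum(v for _, v in pairs))


def _genus_table(
    profiles_by_step: Mapping[str, CommunityProfile],
    aliases: frozenset[str],
) -> pd.DataFrame:
    """Genus x step table of relative abundances (sensu-lato aliased)."""
    cols = {}
    for step, prof in profiles_by_step.items():
        rel = relative_abundance(prof)
        genera = [canonical_genus(prof.genus_of(a), aliases) for a in rel.index]
        cols[step] = rel.groupby(pd.Index(genera, name="genus")).sum()
    return pd.DataFrame(cols).fillna(0.0)


def aggregate_minor_genera(
    lineage: Lineage | Mapping[str, CommunityProfile],
    threshold: float = 0.05,
    aliases: frozenset[str] | None = None,
    steps: Sequence[str] = FERMENTED_STEPS,
) -> pd.DataFrame:
    """Genus-level composition with rare genera pooled into "Other".

    A genus is kept if its relative abundance reaches ``threshold`` in at
    least one step of the lineage's series; genera below the threshold in
    every step are pooled.  Columns (steps) each sum to 1.
    """
    from .io_formats import LACTOBACILLUS_SENSU_LATO_ALIASES

    aliases = aliases if aliases is not None else LACTOBACILLUS_SENSU_LATO_ALIASES
    profiles = (
        lineage.profiles_by_step(steps) if isinstance(lineage, Lineage) else dict(lineage)
    )
    if not profiles:
        return pd.DataFrame()
    table = _genus_table(profiles, aliases)
    keep = table.max(axis=1) >= threshold
    kept = table.loc[keep]
    other = table.loc[~keep].sum(axis=0)
    out = kept.copy()
    out.loc["Other"] = other
    return out


def lab_fraction(
    profile: CommunityProfile,
    lab_genera: frozenset[str] | None = None,
    aliases: frozenset[str] | None = None,
) -> float:
    """Summed relative abundance of lactic-acid-bacteria ASVs.

    Genus membership is evaluated after collapsing the post-2020 split
    genera onto *Lactobacillus* sensu lato.
    """
    from .io_formats import DEFAULT_LAB_GENERA, LACTOBACILLUS_SENSU_LATO_ALIASES

    lab_genera = lab_genera if lab_genera is not None else DEFAULT_LAB_GENERA
    aliases = aliases if aliases is not None else LACTOBACILLUS_SENSU_LATO_ALIASES
    rel = relative_abundance(profile)
    frac = sum(
        float(v)
        for asv, v in rel.items()
        if canonical_genus(profile.genus_of(asv), aliases) in lab_genera
    )
    return float(frac)


def dominant_taxon(
    profile: CommunityProfile,
    dominance_threshold: float = 0.5,
    lab_genera: frozenset[str] | None = None,
    aliases: frozenset[str] | None = None,
) -> str:
    """Dominant community category, or "none" when nothing exceeds the threshold.

    Categories: Lactobacillus sensu lato / Lactococcus / Streptococcus /
    other-LAB / Pseudomonadota.  The maximal category is reported as dominant
    only when its summed relative abundance is strictly above
    ``dominance_threshold`` (default 0.5, i.e. ">50%").
    """
    from .io_formats import DEFAULT_LAB_GENERA, LACTOBACILLUS_SENSU_LATO_ALIASES

    lab_genera = lab_genera if lab_genera is not None else DEFAULT_LAB_GENERA
    aliases = aliases if aliases is not None else LACTOBACILLUS_SENSU_LATO_ALIASES
    rel = relative_abundance(profile)
    totals = dict.fromkeys(DOMINANCE_CATEGORIES[:-1], 0.0)
    for asv, v in rel.items():
        genus = canonical_genus(profile.genus_of(asv), aliases)
        if genus in lab_genera:
            if genus == "Lactobacillus":
                totals["Lactobacillus sensu lato"] += float(v)
            elif genus in ("Lactococcus", "Streptococcus"):
                totals[genus] += float(v)
            else:
                totals["other-LAB"] += float(v)
        elif profile.phylum_of(asv) == "Pseudomonadota":
            totals["Pseudomonadota"] += float(v)
    best = max(totals, key=lambda k: totals[k])
    return best if totals[best] > dominance_threshold else "none"


@dataclass
class DynamicsSummary:
    """Per-lineage community-dynamics summary over the propagation series."""

    lineage_id: str
    richness_series: dict[str, int] = field(default_factory=dict)
    shannon_series: dict[str, float] = field(default_factory=dict)
    bc_adjacent: list[tuple[str, float]] = field(default_factory=list)
    bc_sum: float = float("nan")
    shannon_fluct_sum: float = float("nan")
    richness_fluct_sum: float = float("nan")
    delta_final_ph: list[tuple[str, float]] = field(default_factory=list)
    lab_fraction_series: dict[str, float] = field(default_factory=dict)
    dominant_taxon_series: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def build_dynamics_summary(
    lineage: Lineage,
    config: PipelineConfig | None = None,
    params_by_step: Mapping | None = None,
) -> DynamicsSummary:
    """Assemble the full dynamics summary for one lineage.

    Alpha series cover every fermented step with a profile; BC pairs and
    final-pH deltas are restricted to F2..F6.  ``params_by_step`` (step ->
    AcidificationParams) supplies the final-pH deltas when available.
    """
    config = config or PipelineConfig()
    summary = DynamicsSummary(lineage_id=lineage.lineage_id)

    all_profiles = lineage.profiles_by_step(FERMENTED_STEPS)
    for step, prof in all_profiles.items():
        summary.richness_series[step] = richness(prof)
        summary.shannon_series[step] = shannon(prof, config.shannon_base)
        summary.lab_fraction_series[step] = lab_fraction(
            prof, config.lab_genera, config.lactobacillus_aliases
        )
        summary.dominant_taxon_series[step] = dominant_taxon(
            prof, config.dominance_threshold, config.lab_genera, config.lactobacillus_aliases
        )

    dyn_profiles = lineage.profiles_by_step(DYNAMICS_STEPS)
    summary.bc_adjacent, summary.bc_sum = adjacent_series(dyn_profiles, "braycurtis")
    _, summary.shannon_fluct_sum = adjacent_series(
        all_profiles, "shannon", FERMENTED_STEPS, config.shannon_base
    )
    _, summary.richness_fluct_sum = adjacent_series(all_profiles, "richness", FERMENTED_STEPS)
    if not summary.bc_adjacent:
        summary.flags.append("no_adjacent_pairs")

    if params_by_step:
        from .kinetics import delta_params

        for rec in delta_params(dict(params_by_step)):
            summary.delta_final_ph.append((rec["step_pair"], rec["d_final_ph"]))
    return summary
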