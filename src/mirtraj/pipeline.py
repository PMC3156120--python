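"""End-to-end analysis: preprocess -> PCA -> spherical statistics -> P-values.

An :class:`AnalysisPlan` names the (strain, treatment) groups to analyse,
each with a projection-center day.  The run then

1. restricts the expression matrix to miRs whose mean raw intensity over the
   samples entering the analysis clears the detection threshold,
2. builds per-arm log-ratio series against each strain's naive kidney,
3. optionally applies a digital knockout or restricts to a miR subset,
4. fits one PCA to the pooled time points of all groups and projects each
   series onto the first k components (or analyses the full retained-miR
   space when ``full_dim`` is set),
5. computes, per group, the center-projected directions, the minimal
   enclosing cap, the spherical SD, and a Monte-Carlo directionality
   P-value against a random-walk null matched to the group's direction
   count and ambient dimension,
6. computes, per group pair, the angular separation of the RMS centers, the
   discrimination, and its Monte-Carlo P-value, and, for designated pairs,
   the proximity P-value (test trajectory randomized, reference held fixed).

Default center days follow the biology: sham arms project from the day-0
naive point; the wild-type injured arm projects from day 1 (tissue damage
and expression changes appear after day 1); immunodeficient injured arms
project from day 0 since they show no initial sham response.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace, asdict

import numpy as np

from . import preprocess
from .exceptions import DegenerateDataError, ValidationError
from .io import ExpressionMatrix, SampleSheet
from .montecarlo import (
    NullDistribution,
    null_discrimination_distribution,
    null_proximity_distribution,
    null_radius_distribution,
    p_value_directionality,
    p_value_discrimination,
    p_value_proximity,
)
from .pca import PCProjection, cumulative_variance, fit_pca, project
from .spherical import (
    angular_distance,
    center_projected_directions,
    discrimination as _discrimination_stat,  # noqa: F401 (re-export convenience)
    min_enclosing_circle,
    spherical_sd,
)
from .synthetic_data import WILD_TYPE

__all__ = ["GroupSpec", "AnalysisPlan", "run_analysis", "run_knockout_comparison"]


def default_center_day(strain: str, treatment: str) -> int:
    if treatment == "IRI" and strain == WILD_TYPE:
        return 1
    return 0


@dataclass(frozen=True)
class GroupSpec:
    """One trajectory to analyse: a (strain, treatment) arm and its center day."""

    strain: str
    treatment: str
    center_day: int | None = None

    def resolved_center(self) -> int:
        if self.center_day is not None:
            return int(self.center_day)
        return default_center_day(self.strain, self.treatment)

    @property
    def label(self) -> str:
        return f"{self.strain}/{self.treatment}"


@dataclass(frozen=True)
class AnalysisPlan:
    """Configuration of one full analysis run."""

    groups: tuple
    n_pcs: int = 3
    full_dim: bool = False
    knockout: tuple = ()
    subset: tuple = ()
    n_reps: int = 10000
    seed: int = 0
    floor: float = 200.0
    mean_threshold: float = 200.0
    #: explicit sample IDs for the mean filter; None = samples of this analysis
    filter_samples: tuple | None = None
    include_naive_in_fit: bool = True
    compute_discrimination: bool = True
    #: (test_group_index, reference_group_index) pairs for proximity tests
    proximity_pairs: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "knockout", tuple(self.knockout))
        object.__setattr__(self, "subset", tuple(self.subset))
        object.__setattr__(self, "proximity_pairs",
                           tuple((int(a), int(b)) for a, b in self.proximity_pairs))
        if not self.groups:
            raise ValidationError("plan must name at least one group")
        if self.knockout and self.subset:
            raise ValidationError("knockout and subset modes are mutually exclusive")
        if self.n_pcs < 1:
            raise ValidationError("n_pcs must be >= 1")
        for a, b in self.proximity_pairs:
            if not (0 <= a < len(self.groups) and 0 <= b < len(self.groups)):
                raise ValidationError(f"proximity pair ({a}, {b}) out of range")


def _plan_echo(plan: AnalysisPlan) -> dict:
    echo = asdict(plan)
    echo["groups"] = [
        {"strain": g.strain, "treatment": g.treatment,
         "center_day": g.resolved_center()}
        for g in plan.groups
    ]
    return echo


def _series_seed(base_seed: int, *parts) -> int:
    # process-independent child seed (str hashes are salted, crc32 is stable)
    crcs = [zlib.crc32(repr(p).encode()) for p in parts]
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, *crcs])
    return int(ss.generate_state(1)[0] % (2**31))


def run_analysis(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    plan: AnalysisPlan,
    *,
    null_cache: dict | None = None,
) -> dict:
    """Run the full analysis and return a JSON-serialisable report.

    ``null_cache`` maps null keys to precomputed :class:`NullDistribution`
    objects; entries are added in place so repeated runs (e.g. a knockout
    comparison) share nulls.  Reruns with identical inputs and seed produce
    identical reports.
    """
    for g in plan.groups:
        arm = sheet.samples_for(g.strain, g.treatment)
        if len(arm) == 0:
            raise ValidationError(f"group {g.label!r} has no samples in the sheet")
    if null_cache is None:
        null_cache = {}

    # --- preprocessing -----------------------------------------------------
    strains = sorted({g.strain for g in plan.groups})
    analysis_samples: list[str] = []
    for strain in strains:
        analysis_samples.append(sheet.naive_sample(strain))
    for g in plan.groups:
        analysis_samples.extend(str(s) for s in sheet.samples_for(g.strain, g.treatment)["sample_id"])
    analysis_samples = list(dict.fromkeys(analysis_samples))

    scope = list(plan.filter_samples) if plan.filter_samples is not None else analysis_samples
    retained = preprocess.filter_by_mean(matrix, plan.mean_threshold, scope)
    if plan.subset:
        missing = [m for m in plan.subset if m not in retained.data.index]
        if missing:
            raise ValidationError(
                f"subset miRs absent after the mean filter: {missing}"
            )
        retained = retained.subset_mirs(plan.subset)

    series = {}
    for g in plan.groups:
        s = preprocess.normalize_series(retained, sheet, g.strain, g.treatment, plan.floor)
        if plan.knockout:
            s = preprocess.digital_knockout(s, plan.knockout)
        series[g] = s

    # --- projection --------------------------------------------------------
    fit_vectors = []
    fit_labels = []
    seen = set()
    for g in plan.groups:
        s = series[g]
        for day, vec in zip(s.days, s.vectors):
            if day == 0 and not plan.include_naive_in_fit:
                continue
            key = (s.strain, s.treatment, day)
            # each strain's naive point enters the fit once
            if day == 0:
                key = (s.strain, "naive", 0)
            if key in seen:
                continue
            seen.add(key)
            fit_vectors.append(vec)
            fit_labels.append(f"{s.strain}/{s.treatment}/d{day}")
    fit_vectors = np.array(fit_vectors)

    if plan.full_dim:
        model = None
        k = retained.shape[0]
        projections = {
            g: PCProjection(label=series[g].label, days=tuple(series[g].days),
                            coordinates=series[g].vectors)
            for g in plan.groups
        }
        variance_fractions = None
    else:
        model = fit_pca(fit_vectors, labels=fit_labels)
        k = min(plan.n_pcs, model.n_components)
        projections = {g: project(model, series[g], k=k) for g in plan.groups}
        variance_fractions = model.variance_fractions

    # --- per-group directional statistics ----------------------------------
    group_results = []
    direction_sets = {}
    spreads = {}
    for gi, g in enumerate(plan.groups):
        center_day = g.resolved_center()
        proj = projections[g]
        if center_day not in proj.days:
            raise ValidationError(
                f"center day {center_day} not in days of group {g.label!r}"
            )
        dirs = center_projected_directions(proj, center_day)
        circle = min_enclosing_circle(dirs)
        spread = spherical_sd(dirs)
        direction_sets[g] = dirs
        spreads[g] = spread
        entry = {
            "strain": g.strain,
            "treatment": g.treatment,
            "center_day": center_day,
            "days": list(dirs.labels),
            "n_directions": len(dirs),
            "ambient_dim": dirs.ambient_dim,
            "enclosing_radius_deg": circle.radius_deg,
            "enclosing_center": circle.center,
            "spherical_sd_deg": spread.sd_deg,
            "sd_center": spread.sd_center,
        }
        if plan.n_reps > 0:
            key = ("radius", len(dirs), dirs.ambient_dim)
            if key not in null_cache:
                seed = _series_seed(plan.seed, *key)
                null_cache[key] = null_radius_distribution(
                    len(dirs), dirs.ambient_dim, plan.n_reps, seed=seed
                )
            null = null_cache[key]
            entry["p_directionality"] = p_value_directionality(circle.radius_deg, null)
            entry["null"] = {
                "statistic": null.statistic_name,
                "n_reps": null.n_reps,
                "n_directions": null.n_directions,
                "ambient_dim": null.ambient_dim,
                "seed": null.seed,
                "quantiles": null.quantiles(),
            }
        group_results.append(entry)

    # --- pairwise comparisons ----------------------------------------------
    pair_results = []
    if plan.compute_discrimination and len(plan.groups) > 1:
        for i in range(len(plan.groups)):
            for j in range(i + 1, len(plan.groups)):
                gi, gj = plan.groups[i], plan.groups[j]
                si, sj = spreads[gi], spreads[gj]
                sep = angular_distance(si.sd_center, sj.sd_center)
                m = max(si.sd_deg, sj.sd_deg)
                if m < 1e-12:
                    raise DegenerateDataError(
                        f"both spherical SDs are zero for pair ({gi.label}, {gj.label})"
                    )
                disc = sep / m
                entry = {
                    "a": gi.label, "b": gj.label,
                    "separation_deg": sep,
                    "discrimination": disc,
                }
                if plan.n_reps > 0:
                    # the statistic is symmetric in the two walks, so the
                    # null is keyed (and built) with sorted sizes
                    na, nb = sorted((len(direction_sets[gi]), len(direction_sets[gj])))
                    d = direction_sets[gi].ambient_dim
                    key = ("discrimination", na, nb, d)
                    if key not in null_cache:
                        seed = _series_seed(plan.seed, *key)
                        null_cache[key] = null_discrimination_distribution(
                            na, nb, d, plan.n_reps, seed=seed
                        )
                    entry["p_discrimination"] = p_value_discrimination(
                        disc, na, nb, d, null=null_cache[key]
                    )
                    entry["null_note"] = (
                        "both groups replaced by independent random walks of the "
                        "observed sizes; one-sided P on large discrimination "
                        "(reconstructed null)"
                    )
                pair_results.append(entry)

    proximity_results = []
    per_group_proximity_p = []
    for (ti, ri) in plan.proximity_pairs:
        gt, gr = plan.groups[ti], plan.groups[ri]
        obs = angular_distance(spreads[gt].sd_center, spreads[gr].sd_center)
        entry = {
            "test": gt.label, "reference": gr.label,
            "angle_deg": obs,
        }
        if plan.n_reps > 0:
            nd = len(direction_sets[gt])
            d = direction_sets[gt].ambient_dim
            key = ("proximity", nd, d, gr.label)
            if key not in null_cache:
                seed = _series_seed(plan.seed, *key)
                null_cache[key] = null_proximity_distribution(
                    nd, d, spreads[gr].sd_center, plan.n_reps, seed=seed
                )
            p = p_value_proximity(obs, nd, d, spreads[gr].sd_center,
                                  null=null_cache[key])
            entry["p_proximity"] = p
            entry["null_note"] = (
                "test trajectory replaced by a random walk, reference center "
                "held fixed; P = fraction of replicates at least this close "
                "(reconstructed null)"
            )
            per_group_proximity_p.append(p)
        proximity_results.append(entry)

    report = {
        "config": _plan_echo(plan),
        "seed": plan.seed,
        "n_reps": plan.n_reps,
        "n_retained_mirs": retained.shape[0],
        "ambient_dim": k,
        "mode": "full_dim" if plan.full_dim else f"pca{k}",
        "retained_mir_ids": list(retained.data.index),
        "groups": group_results,
        "pairs": pair_results,
        "proximity": proximity_results,
        "coordinates": [
            {"series": projections[g].label, "day": int(day),
             "coords": projections[g].coordinates[i]}
            for g in plan.groups
            for i, day in enumerate(projections[g].days)
        ],
    }
    if variance_fractions is not None:
        report["variance_fractions"] = variance_fractions
        report["cumulative_variance"] = {
            str(kk): cumulative_variance(model, kk)
            for kk in (1, 3, 9, model.n_components)
            if 1 <= kk <= model.n_components
        }
    if per_group_proximity_p:
        # the joint construction behind the published combined proximity P is
        # unstated; the product of per-group P-values is reported alongside
        report["joint_proximity_p_product"] = float(np.prod(per_group_proximity_p))
    return report


def run_knockout_comparison(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    plan: AnalysisPlan,
    knockout_set,
    *,
    null_cache: dict | None = None,
) -> dict:
    """Paired run with and without a digital knockout, plus deltas."""
    if plan.subset:
        raise ValidationError("knockout comparison cannot use a subset plan")
    if null_cache is None:
        null_cache = {}
    base_plan = replace(plan, knockout=())
    ko_plan = replace(plan, knockout=tuple(knockout_set))
    baseline = run_analysis(matrix, sheet, base_plan, null_cache=null_cache)
    knockout = run_analysis(matrix, sheet, ko_plan, null_cache=null_cache)

    deltas = {
        "radius_deg": {
            g_ko["strain"] + "/" + g_ko["treatment"]:
                g_ko["enclosing_radius_deg"] - g_b["enclosing_radius_deg"]
            for g_b, g_ko in zip(baseline["groups"], knockout["groups"])
        },
        "separation_deg": {
            f"{p_ko['a']}|{p_ko['b']}": p_ko["separation_deg"] - p_b["separation_deg"]
            for p_b, p_ko in zip(baseline["pairs"], knockout["pairs"])
        },
        "discrimination": {
            f"{p_ko['a']}|{p_ko['b']}": p_ko["discrimination"] - p_b["discrimination"]
            for p_b, p_ko in zip(baseline["pairs"], knockout["pairs"])
        },
    }
    return {
        "knockout_set": list(knockout_set),
        "baseline": baseline,
        "knockout": knockout,
        "deltas": deltas,
    }
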