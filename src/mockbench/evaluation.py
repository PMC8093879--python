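"""Comparison of predicted taxonomic profiles against ground truth.

Presence/absence accuracy is summarized by precision P = TP/(TP+FP), recall
R = TP/(TP+FN) and their harmonic mean F1 = 2PR/(P+R), computed on species
sets after an abundance threshold (the benchmark convention removes truth
species below 0.01% as undetectable by most classifiers). Abundance
accuracy is summarized by the L1 (Manhattan) distance — the sum of absolute
per-species differences over the union of species, 0% for identical and
200% for disjoint normalized profiles — and by the mean relative percent
error 100*|T-E|/T over ground-truth species.

The detection limit of a classifier on a sample is the lowest reported
abundance at which filtering the profile achieves a target false discovery
rate FDR = FP/(TP+FP): thresholds are swept in ascending order of the
predicted abundances and the first one meeting the target wins.

Abundances are handled in percent throughout this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_MIN_ABUNDANCE = 0.01  # percent
DEFAULT_TARGET_FDRS = (0.001, 0.01, 0.05, 0.10)


@dataclass(frozen=True)
class AbundanceProfile:
    """Species → abundance mapping with a recorded unit and role.

    ``role`` is one of "truth-reads", "truth-cells" or "prediction";
    ``unit`` is "percent" (canonical) or "fraction".
    """

    abundances: Mapping[str, float]
    unit: str = "percent"
    role: str = "prediction"
    source: str = ""

    def __post_init__(self) -> None:
        if self.unit not in ("percent", "fraction"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        for sp, a in self.abundances.items():
            if a < 0:
                raise ValidationError(f"negative abundance for {sp!r}: {a}")
        object.__setattr__(self, "abundances", dict(self.abundances))

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, float]],
        unit: str = "percent",
        role: str = "prediction",
        source: str = "",
    ) -> "AbundanceProfile":
        seen: dict[str, float] = {}
        for sp, a in pairs:
            if sp in seen:
                raise ValidationError(f"duplicate species {sp!r} in profile")
            seen[sp] = float(a)
        return cls(seen, unit=unit, role=role, source=source)

    def as_percent(self) -> "AbundanceProfile":
        if self.unit == "percent":
            return self
        return AbundanceProfile(
            {s: 100.0 * a for s, a in self.abundances.items()},
            unit="percent",
            role=self.role,
            source=self.source,
        )

    def species(self) -> set[str]:
        return set(self.abundances)

    def get(self, species: str, default: float = 0.0) -> float:
        return self.abundances.get(species, default)

    def total(self) -> float:
        return sum(self.abundances.values())

    def translate(self, mapping: Mapping[str, str]) -> "AbundanceProfile":
        """Rename species ids (e.g. NCBI → GTDB); unmapped labels pass through."""
        out: dict[str, float] = {}
        for sp, a in self.abundances.items():
            new = mapping.get(sp, sp)
            if new in out:
                raise ValidationError(
                    f"translation collapses two species onto {new!r}"
                )
            out[new] = a
        return AbundanceProfile(out, unit=self.unit, role=self.role,
                                source=self.source)

    def __len__(self) -> int:
        return len(self.abundances)

    def items(self):
        return self.abundances.items()


def _coerce(profile) -> AbundanceProfile:
    if isinstance(profile, AbundanceProfile):
        return profile.as_percent()
    return AbundanceProfile.from_pairs(profile.items())


@dataclass(frozen=True)
class ConfusionSummary:
    """Species-level confusion counts at a given abundance threshold."""

    tp: int
    fp: int
    fn: int
    threshold: float
    tp_species: frozenset[str] = frozenset()
    fp_species: frozenset[str] = frozenset()
    fn_species: frozenset[str] = frozenset()


@dataclass
class EvalReport:
    """All evaluation statistics for one (truth, prediction) pair."""

    precision: float
    recall: float
    f1: float
    l1_distance: float  # percent, [0, 200]
    mean_relative_error: float  # percent
    fp_abundance_mass: float  # percent
    fn_abundance_mass: float  # percent
    optimized_threshold: float
    optimized_f1: float
    detection_limits: dict[float, float | None]
    confusion: ConfusionSummary
    min_abundance: float = DEFAULT_MIN_ABUNDANCE
    label: str = ""

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "l1_distance": self.l1_distance,
            "mean_relative_error": self.mean_relative_error,
            "fp_abundance_mass": self.fp_abundance_mass,
            "fn_abundance_mass": self.fn_abundance_mass,
            "optimized_threshold": self.optimized_threshold,
            "optimized_f1": self.optimized_f1,
            "tp": self.confusion.tp,
            "fp": self.confusion.fp,
            "fn": self.confusion.fn,
            "min_abundance": self.min_abundance,
        }
        for fdr, limit in self.detection_limits.items():
            d[f"detection_limit_fdr_{fdr:g}"] = limit
        return d


def filter_profile(profile, min_abundance: float) -> AbundanceProfile:
    """Drop species below ``min_abundance`` percent; keep species at exactly
    the threshold. The surviving abundances are NOT renormalized, so FP/FN
    abundance mass stays on the original scale."""
    p = _coerce(profile)
    return AbundanceProfile(
        {s: a for s, a in p.items() if a >= min_abundance},
        unit="percent",
        role=p.role,
        source=p.source,
    )


def confusion(truth, prediction, threshold: float = 0.0) -> ConfusionSummary:
    """Species-set confusion counts after thresholding both profiles."""
    t = filter_profile(truth, threshold).species()
    p = filter_profile(prediction, threshold).species()
    return ConfusionSummary(
        tp=len(t & p),
        fp=len(p - t),
        fn=len(t - p),
        threshold=threshold,
        tp_species=frozenset(t & p),
        fp_species=frozenset(p - t),
        fn_species=frozenset(t - p),
    )


def precision_recall_f1(c: ConfusionSummary) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

    Empty-denominator conventions: an empty prediction has P = 1 when there
    is nothing to find (FN = 0) and P = 0 otherwise; an empty truth set has
    R = 1; F1 = 0 when P = R = 0.
    """
    if c.tp + c.fp == 0:
        p = 1.0 if c.fn == 0 else 0.0
    else:
        p = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        r = 1.0
    else:
        r = c.tp / (c.tp + c.fn)
    f1 = 0.0 if (p + r) == 0 else 2.0 * p * r / (p + r)
    return p, r, f1


def l1_distance(truth, prediction) -> float:
    """Sum of |T_s - E_s| over the union of species, in percent."""
    t, e = _coerce(truth), _coerce(prediction)
    return sum(
        abs(t.get(s) - e.get(s)) for s in t.species() | e.species()
    )


def relative_errors(truth, prediction) -> tuple[dict[str, float], float]:
    """Per-truth-species relative percent error 100*|T-E|/T, and its mean.

    Truth species absent from the prediction contribute 100% (E = 0);
    predicted species absent from the truth (FPs) are excluded, so the mean
    runs over ground-truth species only.
    """
    t, e = _coerce(truth), _coerce(prediction)
    errors: dict[str, float] = {}
    for sp, ta in t.items():
        if ta <= 0:
            raise ValidationError(
                f"truth abundance for {sp!r} must be > 0, got {ta}"
            )
        errors[sp] = 100.0 * abs(ta - e.get(sp)) / ta
    mean = float(np.mean(list(errors.values()))) if errors else 0.0
    return errors, mean


def fp_fn_abundance(
    truth, prediction, threshold: float = 0.0
) -> tuple[float, float]:
    """(sum of FP predicted abundances, sum of FN truth abundances), percent."""
    t = filter_profile(truth, threshold)
    p = filter_profile(prediction, threshold)
    fp_mass = sum(a for s, a in p.items() if s not in t.species())
    fn_mass = sum(a for s, a in t.items() if s not in p.species())
    return fp_mass, fn_mass


def _candidate_thresholds(prediction: AbundanceProfile) -> list[float]:
    return sorted({0.0} | set(prediction.abundances.values()))


def optimize_f1_threshold(truth, prediction) -> tuple[float, float]:
    """Best single abundance threshold for the prediction, by F1.

    Candidates are 0 plus every distinct predicted abundance; at each, the
    prediction keeps species >= t and F1 is recomputed against the (already
    filtered) truth. Ties go to the lowest threshold.
    """
    t = _coerce(truth)
    p = _coerce(prediction)
    best_t, best_f1 = 0.0, -1.0
    for cand in _candidate_thresholds(p):
        c = confusion(t, filter_profile(p, cand))
        _, _, f1 = precision_recall_f1(c)
        if f1 > best_f1:
            best_t, best_f1 = cand, f1
    return best_t, best_f1


def detection_limit(truth, prediction, target_fdr: float) -> float | None:
    """Lowest abundance threshold achieving FDR <= target, or None.

    FDR = FP/(TP+FP) over species surviving a "keep >= t" filter of the
    prediction; an empty filtered prediction has FDR 0. Candidates are 0
    plus the distinct predicted abundances in ascending order, so a returned
    0 means no filtering is needed. None signals the target is unachievable
    at any threshold (the highest-abundance prediction is a false positive).
    """
    if not 0.0 <= target_fdr <= 1.0:
        raise ValidationError("target_fdr must be in [0, 1]")
    t = _coerce(truth)
    p = _coerce(prediction)
    truth_set = t.species()
    for cand in _candidate_thresholds(p):
        kept = {s for s, a in p.items() if a >= cand}
        if not kept:
            fdr = 0.0
        else:
            fp = len(kept - truth_set)
            fdr = fp / len(kept)
        if fdr <= target_fdr:
            return cand
    return None


def evaluate_profile(
    truth,
    prediction,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
    target_fdrs: Sequence[float] = DEFAULT_TARGET_FDRS,
    label: str = "",
) -> EvalReport:
    """Full evaluation of one prediction against one ground truth.

    The truth is filtered at ``min_abundance`` percent (default 0.01%,
    dropping the undetectable long tail); the prediction is filtered at the
    same threshold for the confusion/mass statistics. Detection limits are
    computed from the unfiltered prediction against the filtered truth.
    """
    t = filter_profile(truth, min_abundance)
    p_raw = _coerce(prediction)
    p = filter_profile(p_raw, min_abundance)

    c = confusion(t, p)
    precision, recall, f1 = precision_recall_f1(c)
    l1 = l1_distance(t, p)
    _, mean_rel = relative_errors(t, p)
    fp_mass, fn_mass = fp_fn_abundance(t, p)
    opt_t, opt_f1 = optimize_f1_threshold(t, p)
    limits = {fdr: detection_limit(t, p_raw, fdr) for fdr in target_fdrs}

    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        l1_distance=l1,
        mean_relative_error=mean_rel,
        fp_abundance_mass=fp_mass,
        fn_abundance_mass=fn_mass,
        optimized_threshold=opt_t,
        optimized_f1=opt_f1,
        detection_limits=limits,
        confusion=c,
        min_abundance=min_abundance,
        label=label,
    )


def aggregate(
    reports_by_class: Mapping[str, Sequence[EvalReport]],
    statistic: str = "mean",
) -> pd.DataFrame:
    """Summarize reports per group (typically per ANI similarity class).

    Produces mean ± sd for precision/recall/F1/L1 and, per target FDR, the
    requested statistic (mean or median) of the detection limit over the
    samples where it was achievable, together with the count of samples
    where it was not. Empty groups are omitted with a warning.
    """
    if statistic not in ("mean", "median"):
        raise ValidationError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median
    rows = []
    for group in reports_by_class:
        reports = list(reports_by_class[group])
        if not reports:
            warnings.warn(f"group {group!r} has no reports; omitted", stacklevel=2)
            continue
        row: dict[str, object] = {"group": group, "n_samples": len(reports)}
        for metric in ("precision", "recall", "f1", "l1_distance",
                       "mean_relative_error", "fp_abundance_mass",
                       "fn_abundance_mass", "optimized_f1"):
            values = [getattr(r, metric) for r in reports]
            row[f"{metric}_mean"] = float(np.mean(values))
            row[f"{metric}_sd"] = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        fdrs = sorted({fdr for r in reports for fdr in r.detection_limits})
        for fdr in fdrs:
            limits = [r.detection_limits.get(fdr) for r in reports]
            achieved = [v for v in limits if v is not None]
            row[f"detection_limit_fdr_{fdr:g}_{statistic}"] = (
                float(agg(achieved)) if achieved else None
            )
            row[f"detection_limit_fdr_{fdr:g}_unachievable"] = (
                len(limits) - len(achieved)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group") if rows else pd.DataFrame()
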