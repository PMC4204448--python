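"""Exhaustive filter search and over-fitting (fragility) diagnostics.

Every candidate spatial-frequency filter on a grid is pushed through the full
pipeline — Fourier filtering of the battery, template matching, affine
scaling to the human reference — and scored by its sum of squared residuals
(SSR).  Brute force is deliberate: no gradient or stochastic optimizer is
used, so the SSR surface itself is available for inspection.

The fragility analysis re-evaluates the best filter's neighbours (small
perturbations of center frequency and bandwidth, with the affine scaling
re-fit per point) and summarises how much the per-condition predictions move:
per-condition prediction ranges across neighbours and the number of
rank-order inversions relative to the optimum's prediction ordering.  A large
dispersion from tiny parameter changes is the signature of over-fitting
rather than a mechanistic account.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decision import TemplatePair, ThresholdPrediction, build_templates, discriminability, scale_to_human
from .fourier_model import FilterSpec, FilterSpecError, build_filter_mask, filter_spectrum
from .stimuli import StimulusBattery

__all__ = [
    "SearchGrid",
    "SearchResult",
    "FragilityReport",
    "BatterySpectra",
    "evaluate_filter",
    "grid_search",
    "fragility_analysis",
]

log = logging.getLogger("crowdbench.search")


@dataclass(frozen=True)
class SearchGrid:
    """Axis specifications (cycles/degree) of an exhaustive filter grid.

    For lowpass/highpass the cutoff axis applies; for bandpass the
    (center_freq x bandwidth) cross product is enumerated and combinations
    whose lower edge would fall below 0 cycles/degree are skipped.
    """

    family: str
    cutoff_min: float = 0.5
    cutoff_max: float = 30.0
    cutoff_step: float = 0.5
    center_min: float = 0.5
    center_max: float = 20.0
    center_step: float = 0.5
    bandwidth_min: float = 0.5
    bandwidth_max: float = 10.0
    bandwidth_step: float = 0.5

    def specs(self) -> list[FilterSpec]:
        def axis(lo, hi, st):
            n = int(np.floor((hi - lo) / st + 1e-9)) + 1
            return [lo + i * st for i in range(n)]

        if self.family in ("lowpass", "highpass"):
            out = [FilterSpec(self.family, cutoff=c)
                   for c in axis(self.cutoff_min, self.cutoff_max, self.cutoff_step)]
        elif self.family == "bandpass":
            out = []
            for c in axis(self.center_min, self.center_max, self.center_step):
                for w in axis(self.bandwidth_min, self.bandwidth_max, self.bandwidth_step):
                    if c - w / 2 >= 0:
                        out.append(FilterSpec("bandpass", center_freq=c, bandwidth=w))
        else:
            raise ValueError(f"unknown family {self.family!r}")
        if not out:
            raise ValueError("empty search grid")
        return out


class BatterySpectra:
    """Precomputed forward transforms of every battery image.

    The grid search evaluates hundreds of masks against the same stimuli, so
    the forward FFTs are computed once and only the mask multiply + inverse
    transform run per candidate.
    """

    def __init__(self, battery: StimulusBattery, width_factor: float = 5.0):
        self.battery = battery
        self.templates: TemplatePair = build_templates(battery.geometry, width_factor)
        self.spectra = {
            label: {d: np.fft.fft2(battery.images[label][d].pixels) for d in ("left", "right")}
            for label in battery.labels
        }

    def scores_for_mask(self, mask) -> dict[str, float]:
        scores = {}
        for label in self.battery.labels:
            responses = {d: filter_spectrum(self.spectra[label][d], mask) for d in ("left", "right")}
            scores[label] = discriminability(responses, self.templates, label).value
        return scores


def _as_vectors(scores: dict[str, float], human: dict[str, float]):
    labels = list(human.keys())
    missing = [l for l in labels if l not in scores]
    if missing:
        raise ValueError(f"conditions missing from model scores: {missing}")
    return labels, np.array([scores[l] for l in labels]), np.array([human[l] for l in labels])


def evaluate_filter(spec: FilterSpec, battery: StimulusBattery | BatterySpectra,
                    human: dict[str, float], width_factor: float = 5.0):
    """SSR and fitted predictions of one filter against the human vector.

    Runs Fourier filtering -> template matching -> affine scaling (re-fit for
    this filter) and returns ``(ssr, predictions_by_label)``.
    """
    spectra = battery if isinstance(battery, BatterySpectra) else BatterySpectra(battery, width_factor)
    mask = build_filter_mask(spec, spectra.battery.images[spectra.battery.labels[0]]["left"].pixels.shape,
                             spectra.battery.geometry.degrees_per_pixel)
    scores = spectra.scores_for_mask(mask)
    labels, s, h = _as_vectors(scores, human)
    fit: ThresholdPrediction = scale_to_human(s, h)
    return fit.ssr, dict(zip(labels, fit.predictions))


@dataclass
class SearchResult:
    """SSR surface over a filter grid plus the argmin."""

    family: str
    table: pd.DataFrame  # one row per grid point: parameters, ssr
    best: FilterSpec
    best_ssr: float
    predictions: dict[FilterSpec, dict[str, float]]

    @property
    def best_predictions(self) -> dict[str, float]:
        return self.predictions[self.best]


def _tie_key(spec: FilterSpec):
    if spec.family == "bandpass":
        return (spec.center_freq, spec.bandwidth)
    return (spec.cutoff,)


def grid_search(grid: SearchGrid, battery: StimulusBattery | BatterySpectra,
                human: dict[str, float], width_factor: float = 5.0,
                progress: bool = False) -> SearchResult:
    """Evaluate every grid point and return the SSR table and the optimum.

    Ties on SSR are broken by lower center/cutoff frequency, then lower
    bandwidth, so the result is a pure function of its inputs.
    """
    spectra = battery if isinstance(battery, BatterySpectra) else BatterySpectra(battery, width_factor)
    specs = grid.specs()
    rows, predictions = [], {}
    best, best_ssr = None, np.inf
    iterator = specs
    if progress:
        from tqdm import tqdm
        iterator = tqdm(specs, desc=f"{grid.family} grid")
    for spec in iterator:
        ssr, preds = evaluate_filter(spec, spectra, human)
        predictions[spec] = preds
        row = {"family": spec.family, "ssr": ssr}
        if spec.family == "bandpass":
            row.update(center_freq=spec.center_freq, bandwidth=spec.bandwidth)
        else:
            row.update(cutoff=spec.cutoff)
        rows.append(row)
        if ssr < best_ssr or (ssr == best_ssr and best is not None and _tie_key(spec) < _tie_key(best)):
            best, best_ssr = spec, ssr
        log.debug("evaluated %s: ssr=%.6g", spec.short_id(), ssr)
    return SearchResult(family=grid.family, table=pd.DataFrame(rows),
                        best=best, best_ssr=float(best_ssr), predictions=predictions)


@dataclass
class FragilityReport:
    """Dispersion of predictions across small perturbations of the optimum.

    ``per_condition_range`` is max - min of each condition's prediction over
    all evaluated neighbours (the optimum included); ``rank_inversions``
    counts, per neighbour, the condition pairs whose prediction ordering is
    inverted relative to the optimum's ordering (discordant pairs).
    """

    optimum: FilterSpec
    neighbor_predictions: dict[FilterSpec, dict[str, float]]
    per_condition_range: dict[str, float]
    rank_inversions: dict[FilterSpec, int]
    skipped: list[tuple[float, float]] = field(default_factory=list)

    @property
    def max_rank_inversions(self) -> int:
        return max(self.rank_inversions.values(), default=0)

    @property
    def max_range(self) -> float:
        return max(self.per_condition_range.values(), default=0.0)


def _discordant_pairs(ref: dict[str, float], other: dict[str, float]) -> int:
    labels = list(ref.keys())
    n = 0
    for a, b in itertools.combinations(labels, 2):
        if (ref[a] - ref[b]) * (other[a] - other[b]) < 0:
            n += 1
    return n


def fragility_analysis(best: FilterSpec, deltas, battery: StimulusBattery | BatterySpectra,
                       human: dict[str, float], width_factor: float = 5.0) -> FragilityReport:
    """Probe the optimum's neighbourhood: best +/- each delta on both axes.

    For a bandpass optimum the (center + dc, bandwidth + dw) cross product is
    evaluated for dc, dw in deltas (0 included to anchor the optimum itself);
    for lowpass/highpass the cutoff axis is probed.  The affine scaling is
    re-fit per neighbour.  Neighbours that are not valid filters are skipped
    and reported.
    """
    spectra = battery if isinstance(battery, BatterySpectra) else BatterySpectra(battery, width_factor)
    ds = sorted({0.0} | {float(d) for d in deltas} | {-float(d) for d in deltas})
    preds: dict[FilterSpec, dict[str, float]] = {}
    skipped: list[tuple[float, float]] = []

    if best.family == "bandpass":
        offsets = list(itertools.product(ds, ds))
        for dc, dw in offsets:
            try:
                spec = FilterSpec("bandpass", center_freq=best.center_freq + dc,
                                  bandwidth=best.bandwidth + dw)
            except FilterSpecError:
                skipped.append((dc, dw))
                log.info("skipping invalid neighbour dc=%+g dw=%+g", dc, dw)
                continue
            _, preds[spec] = evaluate_filter(spec, spectra, human)
    else:
        for dc in ds:
            try:
                spec = FilterSpec(best.family, cutoff=best.cutoff + dc)
            except FilterSpecError:
                skipped.append((dc, 0.0))
                continue
            _, preds[spec] = evaluate_filter(spec, spectra, human)

    ref = preds[best]
    labels = list(ref.keys())
    per_cond = {
        l: max(p[l] for p in preds.values()) - min(p[l] for p in preds.values())
        for l in labels
    }
    inversions = {spec: _discordant_pairs(ref, p) for spec, p in preds.items()}
    return FragilityReport(optimum=best, neighbor_predictions=preds,
                           per_condition_range=per_cond, rank_inversions=inversions,
                           skipped=skipped)
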