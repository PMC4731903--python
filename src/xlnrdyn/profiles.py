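"""Qualitative classification of transcription time courses.

Four recurring response shapes are distinguished:

* **C1** — monotone increase toward saturation;
* **C2** — a single maximum followed by decline to a lower plateau
  (induction, then repression and/or xylose depletion);
* **C3** — rise, fall, then a renewed rise that persists to the end of
  the observation window (de-repression of transcription);
* **C4** — two prominent maxima separated by a trough (bimodal
  expression with de-repression, e.g. peaks near 1 h and 3 h).

Anything else is UNCLASSIFIED. The rules operate on a median-smoothed
series with a prominence floor tied to replicate noise, so the labels
are invariant to positive rescaling of the expression axis and robust
to sub-threshold wiggles. The observation window splits into an early
induction window W1 and a late de-repression window W2 at the first
detected trough.

:func:`pattern_generability` asks which of the four shapes the
antagonistic-Hill model can actually produce on a fixed parameter grid —
probing the hypothesis that the C3/C4 shapes lie outside the model's
repertoire.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .data import TimeCourse
from .kinetics import KineticParameters, InputSignal, simulate

__all__ = [
    "ProfileClass",
    "ClassifierConfig",
    "classify_profile",
    "classify_series",
    "pattern_generability",
    "GenerabilityReport",
]

LABELS = ("C1", "C2", "C3", "C4", "UNCLASSIFIED")


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable thresholds of the shape classifier.

    ``range_frac`` — a peak/trough must stand out by at least this
    fraction of the series range; ``noise_sd`` (or the replicate SDs of
    the input course) raises that floor when noise is larger;
    ``default_window_split`` — W1/W2 boundary used when no trough exists.
    """

    range_frac: float = 0.10
    noise_sd: float | None = None
    default_window_split: float = 2.5
    min_points: int = 5


@dataclass(frozen=True)
class ProfileClass:
    """Classification outcome with the features that determined it."""

    label: str
    features: Mapping[str, float] = field(default_factory=dict)
    windows: tuple[float, float] | None = None  # (W1 end, series end)


def _smooth(y: np.ndarray) -> np.ndarray:
    return median_filter(y, size=3, mode="nearest")


def classify_series(
    times: np.ndarray,
    values: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    noise_sd: float | None = None,
) -> ProfileClass:
    """Classify a raw (time, value) series; see the module docstring."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if y.size < config.min_points:
        raise ValueError(f"need >= {config.min_points} points, got {y.size}")

    s = _smooth(y)
    rng_ = float(s.max() - s.min())
    noise = noise_sd if noise_sd is not None else (config.noise_sd or 0.0)
    prom = max(noise, config.range_frac * rng_)
    if rng_ == 0.0:
        return ProfileClass("C1", {"terminal_trend": 0.0},
                            (config.default_window_split, float(times[-1])))

    peaks, _ = find_peaks(s, prominence=prom)
    troughs, _ = find_peaks(-s, prominence=prom)
    terminal = float(s[-1] - s[-2])

    feats: dict[str, float] = {
        "n_peaks": float(len(peaks)),
        "terminal_trend": float(np.sign(terminal)),
    }
    if len(peaks):
        feats["first_peak_time"] = float(times[peaks[0]])
        feats["first_peak_value"] = float(s[peaks[0]])
    if len(troughs):
        feats["trough_time"] = float(times[troughs[0]])
        feats["trough_value"] = float(s[troughs[0]])
    w_split = float(times[troughs[0]]) if len(troughs) else config.default_window_split
    windows = (w_split, float(times[-1]))

    if len(peaks) == 0:
        # monotone within tolerance: sub-threshold dips do not break C1
        drops = np.diff(s)
        max_drop_run = 0.0
        run = 0.0
        for d in drops:
            run = run - d if d < 0 else 0.0
            max_drop_run = max(max_drop_run, run)
        if s[-1] >= s[0] and max_drop_run <= prom:
            return ProfileClass("C1", feats, windows)
        return ProfileClass("UNCLASSIFIED", feats, windows)

    if len(peaks) >= 2:
        between_trough = any(p1 < t < p2 for t in troughs
                             for p1, p2 in zip(peaks, peaks[1:]))
        if between_trough:
            return ProfileClass("C4", feats, windows)

    # single prominent maximum
    p = peaks[0]
    after = s[p:]
    trough_rel = int(np.argmin(after))
    trough_val = float(after[trough_rel])
    renewed = float(s[-1] - trough_val)
    feats["post_peak_min"] = trough_val
    if trough_rel > 0 and trough_rel < after.size - 1 and renewed >= prom and terminal >= 0:
        return ProfileClass("C3", feats, windows)
    if s[-1] <= s[p] - prom:
        return ProfileClass("C2", feats, windows)
    return ProfileClass("UNCLASSIFIED", feats, windows)


def classify_profile(
    tc: TimeCourse, config: ClassifierConfig = ClassifierConfig()
) -> ProfileClass:
    """Classify one measured time course, using its replicate SDs as the
    noise floor for peak prominence."""
    noise = config.noise_sd
    if noise is None:
        noise = float(np.median(tc.sd)) if np.any(tc.sd > 0) else 0.0
    return classify_series(tc.times, tc.mean, config, noise_sd=noise)


def classification_table(
    tcs: Sequence[TimeCourse], config: ClassifierConfig = ClassifierConfig()
) -> pd.DataFrame:
    rows = []
    for tc in tcs:
        pc = classify_profile(tc, config)
        rows.append({
            "gene": tc.gene,
            "strain": tc.strain,
            "xylose_mM": tc.condition,
            "class": pc.label,
            "first_peak_time_h": pc.features.get("first_peak_time", np.nan),
            "trough_time_h": pc.features.get("trough_time", np.nan),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Which shapes can the model generate?
# ---------------------------------------------------------------------------

@dataclass
class GenerabilityReport:
    """Reachability of each profile class over a simulated parameter grid."""

    reachable: dict[str, bool]
    witnesses: dict[str, dict]
    n_cells: int
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"class": c, "reachable": self.reachable[c], "count": self.counts[c]}
             for c in LABELS]
        )


def default_param_grid() -> list[KineticParameters]:
    """Deterministic grid spanning activation/repression/decay regimes."""
    grid = []
    base = KineticParameters()
    for K_i1 in (0.05, 0.2, 0.6):
        for K_i2 in (0.2, 1.0, 50.0):  # 50 ~ repression effectively off
            for k_id in (0.3, 1.0, 3.0):
                for h1 in (1, 2, 4):
                    grid.append(base.replace(K_i1=K_i1, K_i2_Wt=K_i2,
                                             k_id=k_id, h1=h1))
    return grid


def default_u_scenarios() -> list[InputSignal]:
    from .synthetic import xylose_profile

    return [
        xylose_profile(1.0),
        xylose_profile(50.0),
        xylose_profile(1.0, kind="constant"),
    ]


def pattern_generability(
    param_grid: Sequence[KineticParameters] | None = None,
    u_scenarios: Sequence[InputSignal] | None = None,
    times: np.ndarray | None = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> GenerabilityReport:
    """Simulate every (parameter, input) cell and classify the trajectory.

    Traversal order is fixed (parameters outer, inputs inner), so the
    report and its witnesses are fully reproducible. Noiseless
    trajectories are classified with a zero noise floor.
    """
    param_grid = list(param_grid) if param_grid is not None else default_param_grid()
    u_scenarios = list(u_scenarios) if u_scenarios is not None else default_u_scenarios()
    times = np.linspace(0.0, 5.0, 16) if times is None else np.asarray(times)

    reachable = {c: False for c in LABELS}
    witnesses: dict[str, dict] = {}
    counts = {c: 0 for c in LABELS}
    n = 0
    for params in param_grid:
        for u in u_scenarios:
            n += 1
            traj = simulate(params, u, times, strain="Wt", rtol=1e-7, atol=1e-9)
            pc = classify_series(times, traj["x_i"].to_numpy(), config, noise_sd=0.0)
            counts[pc.label] += 1
            if not reachable[pc.label]:
                reachable[pc.label] = True
                witnesses[pc.label] = {
                    "params": params.to_dict(),
                    "input": {"kind": u.kind, "u0": u.u0,
                              "decay_rate": u.decay_rate},
                }
    return GenerabilityReport(reachable, witnesses, n, counts)
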