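"""Synthetic RT-qPCR time-course generator emulating the bioreactor study.

The generator reproduces the study design: the wild type (N400) sampled
every 20 min over 5 h for 23 genes, the CreA partial loss-of-function
mutant (NW283) sampled hourly over 5 h for 8 genes, induction with 1 mM
and 50 mM D-xylose, three biological replicates, expression normalized
to a reference gene. Xylose is depleted over the run: the 1 mM pulse is
essentially exhausted by 5 h while the 50 mM pulse only falls to about
38 mM (roughly 76 % left).

Measurement noise is multiplicative lognormal — the qPCR-typical model —
with a configurable coefficient of variation; replicate means and SDs
are reported exactly as a normalized qPCR table would be. Ground truth
(every parameter, every seed) is recorded alongside the data so that
estimation round-trips can be scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data import TimeCourse, write_timecourses
from .kinetics import InputSignal, KineticParameters, THETA1_DEFAULT, simulate

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "SyntheticDataset",
    "xylose_profile",
    "generate_regulon",
    "WT_DESIGN",
    "MT_DESIGN",
]

#: depletion rates calibrated to the bioreactor HPLC measurements:
#: 50 mM falls to 38 mM by 5 h; 1 mM is nearly exhausted (0.04 mM at 5 h).
RHO_50MM = math.log(50.0 / 38.0) / 5.0
RHO_1MM = math.log(25.0) / 5.0


def xylose_profile(condition_mM: float, kind: str = "exp",
                   seed: int | None = None, horizon: float = 5.0,
                   n_knots: int = 11, jitter: float = 0.0) -> InputSignal:
    """Xylose input u(t) for an induction condition.

    Exponential decay by default; ``kind="interp"`` samples the decay at
    ``n_knots`` evenly spaced times (optionally jittered measurement
    noise, seeded) and interpolates linearly, mimicking HPLC monitoring.
    """
    if condition_mM <= 0:
        raise ValueError("xylose condition must be positive (mM)")
    rho = RHO_1MM if condition_mM <= 5.0 else RHO_50MM
    if kind == "constant":
        return InputSignal("constant", u0=condition_mM)
    if kind == "exp":
        return InputSignal("exp", u0=condition_mM, decay_rate=rho)
    if kind == "interp":
        t = np.linspace(0.0, horizon, n_knots)
        c = condition_mM * np.exp(-rho * t)
        if jitter > 0:
            rng = np.random.default_rng(seed)
            c = c * np.exp(rng.normal(0.0, jitter, size=c.size))
            c = np.minimum.accumulate(np.clip(c, 0.0, condition_mM))
            c[0] = condition_mM
        return InputSignal("interp", u0=condition_mM,
                           knots=tuple(zip(t.tolist(), c.tolist())))
    raise ValueError(f"unknown profile kind {kind!r}")


@dataclass(frozen=True)
class SyntheticDesign:
    """Sampling design of one strain's induction experiment."""

    strain: str = "Wt"
    n_genes: int = 23
    sampling_interval: float = 1.0 / 3.0  # h; 20 min for the Wt
    horizon: float = 5.0
    conditions: tuple[float, ...] = (1.0, 50.0)
    noise_sd_frac: float = 0.1
    n_replicates: int = 3
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {"C1": 0.5, "C2": 0.5, "C3": 0.0, "C4": 0.0}
    )
    include_xlnr_series: bool = True
    include_decoy: bool = False
    seed: int = 0

    def __post_init__(self):
        n_int = self.horizon / self.sampling_interval
        if abs(n_int - round(n_int)) > 1e-9:
            raise ValueError("horizon must be an integer number of intervals")
        if self.noise_sd_frac < 0:
            raise ValueError("noise fraction must be >= 0")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")

    @property
    def times(self) -> np.ndarray:
        n = round(self.horizon / self.sampling_interval)
        return np.linspace(0.0, self.horizon, n + 1)


WT_DESIGN = SyntheticDesign()
MT_DESIGN = SyntheticDesign(strain="Mt", n_genes=8, sampling_interval=1.0)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters: a shared theta1 block plus per-gene samplers.

    Per-gene theta2 = (k_is_Wt, K_i1, K_i2_Wt, k_id) is drawn log-uniform
    within the given ranges; the mutant is a partial loss of function,
    generated with an enlarged repression threshold
    K_i2_Mt = ``ki2_mt_factor`` * K_i2_Wt and a de-repressed maximal rate
    k_is_Mt = ``lambda_fold`` * k_is_Wt.
    """

    theta1: Mapping[str, float] = field(default_factory=lambda: dict(THETA1_DEFAULT))
    k_is_range: tuple[float, float] = (4.0, 40.0)
    K_i1_range: tuple[float, float] = (0.05, 0.15)
    K_i2_range: tuple[float, float] = (15.0, 60.0)
    k_id_range: tuple[float, float] = (0.5, 4.0)
    lambda_fold: float = 3.0
    ki2_mt_factor: float = 3.0
    h1: float = 2
    h2: float = 4
    x_xlnR_const: float = 1.0

    def sample_gene(self, rng: np.random.Generator) -> KineticParameters:
        def lu(lo_hi):
            lo, hi = lo_hi
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        k_is = lu(self.k_is_range)
        k_i2 = lu(self.K_i2_range)
        return KineticParameters(
            **self.theta1,
            k_is_Wt=k_is,
            k_is_Mt=self.lambda_fold * k_is,
            K_i1=lu(self.K_i1_range),
            K_i2_Wt=k_i2,
            K_i2_Mt=self.ki2_mt_factor * k_i2,
            k_id=lu(self.k_id_range),
            h1=self.h1,
            h2=self.h2,
            x_xlnR_const=self.x_xlnR_const,
        )


@dataclass
class SyntheticDataset:
    """Generated time courses plus the complete truth record."""

    timecourses: list[TimeCourse]
    truth: dict
    design: SyntheticDesign

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None):
        write_timecourses(self.timecourses, csv_path)
        if truth_path is not None:
            Path(truth_path).write_text(json.dumps(self.truth, indent=2, sort_keys=True))

    def gene_params(self, gene: str) -> KineticParameters:
        return KineticParameters.from_dict(self.truth["genes"][gene])


def _noisy_replicates(y: np.ndarray, frac: float, n_rep: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of n_rep mean-corrected lognormal replicates around y."""
    if frac == 0:
        return y.copy(), np.zeros_like(y)
    sigma = math.sqrt(math.log(1.0 + frac * frac))
    noise = rng.lognormal(-0.5 * sigma * sigma, sigma, size=(n_rep, y.size))
    reps = y[None, :] * noise
    sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.zeros(y.size)
    return reps.mean(axis=0), sd


def generate_regulon(
    design: SyntheticDesign = WT_DESIGN,
    truth: GroundTruth = GroundTruth(),
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate a regulon's RT-qPCR dataset under the study design.

    Every gene is integrated with the reference solver under both
    induction conditions from a resting initial state (pre-growth on
    sorbitol: no complex, no CreA, negligible basal transcript), then
    observed through the replicate noise model. A near-constant
    "xlnR-like" series (level ~1.5 normalized units) and, optionally, a
    decoy gene that does not respond to xylose can be appended.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = design.times
    genes = [f"gene{g:02d}" for g in range(1, design.n_genes + 1)]

    tcs: list[TimeCourse] = []
    truth_genes: dict[str, dict] = {}
    for gene in genes:
        params = truth.sample_gene(rng)
        truth_genes[gene] = params.to_dict()
        for cond in design.conditions:
            u = xylose_profile(cond)
            traj = simulate(params, u, times, strain=design.strain)
            mean, sd = _noisy_replicates(traj["x_i"].to_numpy(),
                                         design.noise_sd_frac,
                                         design.n_replicates, rng)
            tcs.append(TimeCourse(gene, design.strain, cond, times, mean, sd,
                                  design.n_replicates))

    if design.include_xlnr_series:
        level = 1.5  # constitutive xlnR stays at ~1-2 normalized units
        for cond in design.conditions:
            base = np.full_like(times, level)
            mean, sd = _noisy_replicates(base, design.noise_sd_frac,
                                         design.n_replicates, rng)
            tcs.append(TimeCourse("xlnR", design.strain, cond, times, mean, sd,
                                  design.n_replicates))
    if design.include_decoy:
        # xylose-indifferent transcript: slow autonomous relaxation to 1.0
        for cond in design.conditions:
            base = 1.0 + 0.5 * np.exp(-0.5 * times)
            mean, sd = _noisy_replicates(base, design.noise_sd_frac,
                                         design.n_replicates, rng)
            tcs.append(TimeCourse("decoy", design.strain, cond, times, mean, sd,
                                  design.n_replicates))

    record = {
        "design": {**asdict(design), "class_mix": dict(design.class_mix)},
        "seed": seed,
        "theta1": dict(truth.theta1),
        "lambda_fold": truth.lambda_fold,
        "ki2_mt_factor": truth.ki2_mt_factor,
        "genes": truth_genes,
    }
    return SyntheticDataset(tcs, record, design)


def generate_study(
    wt_design: SyntheticDesign = WT_DESIGN,
    mt_design: SyntheticDesign = MT_DESIGN,
    truth: GroundTruth = GroundTruth(),
    seed: int = 0,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Paired wild-type + mutant datasets sharing one set of gene truths.

    As in the study, the mutant panel is a subset of the wild-type panel:
    the first ``mt_design.n_genes`` genes. One parameter draw per gene
    drives both strains, so de-repression fold-changes are meaningful.
    """
    if mt_design.n_genes > wt_design.n_genes:
        raise ValueError("mutant panel cannot exceed the wild-type panel")
    ss = np.random.SeedSequence(seed)
    s_draw, s_wt, s_mt = ss.spawn(3)
    rng = np.random.default_rng(s_draw)
    shared = [truth.sample_gene(rng) for _ in range(wt_design.n_genes)]

    def build(design: SyntheticDesign, child) -> SyntheticDataset:
        rng_d = np.random.default_rng(child)
        times = design.times
        tcs, truth_genes = [], {}
        for g in range(design.n_genes):
            gene = f"gene{g + 1:02d}"
            params = shared[g]
            truth_genes[gene] = params.to_dict()
            for cond in design.conditions:
                traj = simulate(params, xylose_profile(cond), times,
                                strain=design.strain)
                mean, sd = _noisy_replicates(traj["x_i"].to_numpy(),
                                             design.noise_sd_frac,
                                             design.n_replicates, rng_d)
                tcs.append(TimeCourse(gene, design.strain, cond, times, mean,
                                      sd, design.n_replicates))
        record = {
            "design": {**asdict(design), "class_mix": dict(design.class_mix)},
            "seed": seed,
            "theta1": dict(truth.theta1),
            "lambda_fold": truth.lambda_fold,
            "ki2_mt_factor": truth.ki2_mt_factor,
            "genes": truth_genes,
        }
        return SyntheticDataset(tcs, record, design)

    return build(wt_design, s_wt), build(mt_design, s_mt)
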