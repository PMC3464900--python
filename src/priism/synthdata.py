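"""Synthetic diel expression generator with known ground truth.

Emulates a cold-stress-style time-course experiment: log-scale baselines,
~24-h sinusoidal clock components with gene-specific phase and amplitude,
additive Gaussian noise, and — in the treatment condition only — a slow
logistic upregulation trend for a planted responder subset plus circadian
disruption (amplitude damping, phase shift, period lengthening) for every
clock-influenced gene.  Each emitted value is the exact sum of the stored
baseline, trend, sinusoid and noise parts, so every pipeline stage can be
checked against planted truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .clockband import CORE_CLOCK_GENES
from .preprocess import ExpressionMatrix, write_expression

__all__ = ["SimConfig", "GroundTruth", "simulate", "write_fixture", "load_truth"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror a 0-58 h course sampled every 2 h under a 16L:8D
    photoperiod: 200 genes of which 8 are core clock genes and 30 are planted
    treatment responders; a 24-h control clock period lengthened to 28 h,
    damped to 60% amplitude and phase-shifted by 4 h under treatment; a
    logistic responder trend of 2.0 log2 units with midpoint 26 h; and
    additive Gaussian noise of sd 0.3 log2 units.
    """

    n_genes: int = 200
    n_clock_genes: int = 8
    n_responders: int = 30
    t_start_h: float = 0.0
    t_end_h: float = 58.0
    step_h: float = 2.0
    clock_period_h: float = 24.0
    treatment_period_h: float = 28.0
    damping: float = 0.6
    phase_shift_h: float = 4.0
    effect_log2: float = 2.0
    effect_midpoint_h: float = 26.0
    effect_rise_h: float = 4.0
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.0, 10.0)
    clock_amplitude_range: tuple[float, float] = (1.5, 2.5)
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_clock_genes + self.n_responders > self.n_genes:
            raise ValueError("clock genes plus responders exceed total genes")
        if min(self.n_genes, self.n_clock_genes) < 1 or self.n_responders < 0:
            raise ValueError("invalid gene counts")
        if self.clock_period_h <= 0 or self.treatment_period_h <= 0:
            raise ValueError("periods must be positive")

    @property
    def times_h(self) -> np.ndarray:
        n = int(round((self.t_end_h - self.t_start_h) / self.step_h))
        return self.t_start_h + self.step_h * np.arange(n + 1)


@dataclass
class GroundTruth:
    """Planted components per gene and condition; parts sum to emitted values."""

    clock_gene_ids: list[str]
    responder_ids: list[str]
    baseline: dict[str, float]
    trend: dict[str, dict[str, np.ndarray]]
    sinusoid: dict[str, dict[str, np.ndarray]]
    noise: dict[str, dict[str, np.ndarray]]
    config: SimConfig = field(repr=False, default=None)


def _gene_ids(cfg: SimConfig) -> tuple[list[str], list[str], list[str]]:
    clock = [
        CORE_CLOCK_GENES[i] if i < len(CORE_CLOCK_GENES) else f"CLOCK{i + 1:02d}"
        for i in range(cfg.n_clock_genes)
    ]
    responders = [f"RESP{i + 1:03d}" for i in range(cfg.n_responders)]
    n_bg = cfg.n_genes - cfg.n_clock_genes - cfg.n_responders
    background = [f"GENE{i + 1:04d}" for i in range(n_bg)]
    return clock, responders, background


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate paired control/treatment matrices plus ground truth.

    Control: baseline + A sin(2 pi t / period + phi) + noise.  Treatment
    additionally damps, phase-shifts and period-lengthens every sinusoid, and
    adds the logistic responder trend.  Fixing the seed makes the output
    bit-reproducible.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times_h
    clock_ids, resp_ids, bg_ids = _gene_ids(cfg)
    gene_ids = clock_ids + resp_ids + bg_ids

    baseline = {}
    trend = {"control": {}, "treatment": {}}
    sinusoid = {"control": {}, "treatment": {}}
    noise = {"control": {}, "treatment": {}}
    values = {"control": np.empty((len(gene_ids), t.size)),
              "treatment": np.empty((len(gene_ids), t.size))}

    for i, gene in enumerate(gene_ids):
        base = rng.uniform(*cfg.baseline_range)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp_range = (
            cfg.clock_amplitude_range if gene in clock_ids else cfg.amplitude_range
        )
        amp = rng.uniform(*amp_range)
        baseline[gene] = base

        sin_ctrl = amp * np.sin(2.0 * np.pi * t / cfg.clock_period_h + phase)
        shifted_phase = phase + 2.0 * np.pi * cfg.phase_shift_h / cfg.treatment_period_h
        sin_trt = (
            cfg.damping
            * amp
            * np.sin(2.0 * np.pi * t / cfg.treatment_period_h + shifted_phase)
        )
        if cfg.noise_sd > 0:
            eps_ctrl = rng.normal(0.0, cfg.noise_sd, t.size)
            eps_trt = rng.normal(0.0, cfg.noise_sd, t.size)
        else:
            eps_ctrl = np.zeros(t.size)
            eps_trt = np.zeros(t.size)
        if gene in resp_ids:
            rise = cfg.effect_log2 / (
                1.0 + np.exp(-(t - cfg.effect_midpoint_h) / cfg.effect_rise_h)
            )
        else:
            rise = np.zeros(t.size)

        # With no disruption, no responders and no noise the two conditions
        # must coincide exactly.
        disrupted = (
            cfg.damping != 1.0
            or cfg.phase_shift_h != 0.0
            or cfg.treatment_period_h != cfg.clock_period_h
        )
        if not disrupted:
            sin_trt = sin_ctrl.copy()

        trend["control"][gene] = np.zeros(t.size)
        trend["treatment"][gene] = rise
        sinusoid["control"][gene] = sin_ctrl
        sinusoid["treatment"][gene] = sin_trt
        noise["control"][gene] = eps_ctrl
        noise["treatment"][gene] = eps_trt
        values["control"][i] = base + sin_ctrl + eps_ctrl
        values["treatment"][i] = base + rise + sin_trt + eps_trt

    control = ExpressionMatrix(gene_ids, t, "control", values["control"])
    treatment = ExpressionMatrix(gene_ids, t, "treatment", values["treatment"])
    truth = GroundTruth(clock_ids, resp_ids, baseline, trend, sinusoid, noise, cfg)
    return control, treatment, truth


def write_fixture(
    outdir, control: ExpressionMatrix, treatment: ExpressionMatrix, truth: GroundTruth
) -> dict[str, Path]:
    """Serialize a simulated experiment: control.tsv, treatment.tsv, gold.txt, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "control": outdir / "control.tsv",
        "treatment": outdir / "treatment.tsv",
        "gold": outdir / "gold.txt",
        "truth": outdir / "truth.json",
    }
    write_expression(paths["control"], control)
    write_expression(paths["treatment"], treatment)
    paths["gold"].write_text("\n".join(truth.responder_ids) + "\n")
    blob = {
        "clock_gene_ids": truth.clock_gene_ids,
        "responder_ids": truth.responder_ids,
        "baseline": truth.baseline,
        "trend": _to_lists(truth.trend),
        "sinusoid": _to_lists(truth.sinusoid),
        "noise": _to_lists(truth.noise),
        "config": asdict(truth.config) if truth.config else None,
    }
    paths["truth"].write_text(json.dumps(blob))
    return paths


def load_truth(path) -> GroundTruth:
    """Reload a truth.json written by :func:`write_fixture`."""
    blob = json.loads(Path(path).read_text())
    cfg = blob.get("config")
    if cfg is not None:
        for key in ("baseline_range", "clock_amplitude_range", "amplitude_range"):
            cfg[key] = tuple(cfg[key])
        cfg = SimConfig(**cfg)
    return GroundTruth(
        blob["clock_gene_ids"],
        blob["responder_ids"],
        blob["baseline"],
        _to_arrays(blob["trend"]),
        _to_arrays(blob["sinusoid"]),
        _to_arrays(blob["noise"]),
        cfg,
    )


def _to_lists(d: dict[str, dict[str, np.ndarray]]):
    return {c: {g: np.asarray(v).tolist() for g, v in genes.items()}
            for c, genes in d.items()}


def _to_arrays(d):
    return {c: {g: np.asarray(v, dtype=float) for g, v in genes.items()}
            for c, genes in d.items()}
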