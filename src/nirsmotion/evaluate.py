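"""HRF-recovery metrics, paired statistics, and the method-comparison
benchmark that reruns the correction-method comparison on synthetic runs.

The benchmark pipeline per run and method is fixed:
intensity -> OD -> (detect +) correct -> band-pass -> MBLL -> block average,
then MSE and Pearson correlation of the recovered mean HRF against the
injected ground truth, per SD pair and chromophore, over the post-stimulus
window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .core import ODSeries, ValidationError
from .correct import (
    SplineParams,
    TPCAParams,
    WaveletParams,
    pca_correct_full,
    spline_correct,
    tpca_correct,
    wavelet_correct,
)
from .detect import DetectionParams, detect_motion_by_channel
from .preprocess import (
    BlockAverageParams,
    FilterParams,
    bandpass,
    block_average,
    intensity_to_od,
    od_to_concentration,
)
from .synth import GeneratorConfig, GroundTruth, generate_run, hrf_value

logger = logging.getLogger("nirsmotion")

__all__ = [
    "BenchmarkConfig", "BenchmarkResult", "PipelineParams",
    "mse", "pearson", "paired_ttest", "apply_correction", "process_run",
    "run_benchmark", "summarize",
]

METHODS = ("none", "spline", "wavelet", "tpca", "pca")

#: Cap reported in place of an infinite t statistic (zero-variance shift).
T_CAP = 1e12


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def mse(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error between two equal-length curves."""
    est, truth = np.asarray(est, float), np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValidationError("curves must have equal length")
    return float(np.mean((est - truth) ** 2))


def pearson(est: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation and its square.

    The squared value is what the comparison reports as R^2.
    """
    est, truth = np.asarray(est, float), np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValidationError("curves must have equal length")
    if np.std(est) == 0 or np.std(truth) == 0:
        raise ValidationError("correlation undefined for a constant series")
    r = float(np.corrcoef(est, truth)[0, 1])
    return r, r * r


def paired_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t test on the differences ``a - b``.

    Identical inputs return (0, 1).  A constant non-zero difference has
    infinite t; it is reported as a sign-capped statistic with p = 0.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return float(np.sign(d[0]) * T_CAP), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# per-run pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineParams:
    detection: DetectionParams = field(default_factory=DetectionParams)
    spline: SplineParams = field(default_factory=SplineParams)
    wavelet: WaveletParams = field(default_factory=WaveletParams)
    tpca: TPCAParams = field(default_factory=TPCAParams)
    filter: FilterParams = field(default_factory=FilterParams)
    block: BlockAverageParams = field(default_factory=BlockAverageParams)
    skip_bandpass: bool = False


def apply_correction(od: ODSeries, method: str,
                     pp: PipelineParams | None = None) -> ODSeries:
    """Dispatch one correction method on an OD series."""
    pp = pp or PipelineParams()
    if method == "none":
        return od
    if method == "spline":
        mask = detect_motion_by_channel(od, pp.detection)
        return spline_correct(od, mask, pp.spline, pp.detection)[0]
    if method == "wavelet":
        return wavelet_correct(od, pp.wavelet)[0]
    if method == "tpca":
        return tpca_correct(od, pp.detection, pp.tpca)[0]
    if method == "pca":
        return pca_correct_full(od, nsv=pp.tpca.nsv, center=pp.tpca.center)[0]
    raise ValidationError(f"unknown correction method '{method}'")


def process_run(rec, truth: GroundTruth, method: str,
                pp: PipelineParams | None = None,
                mbll=None) -> pd.DataFrame:
    """Run the fixed pipeline for one method and score HRF recovery.

    Returns one row per (SD pair, chromophore) with mse (uM^2), r and r2
    computed over the post-stimulus ``[0, post_s)`` window against the
    injected ground-truth HRF.
    """
    pp = pp or PipelineParams()
    od = intensity_to_od(rec)
    od = apply_correction(od, method, pp)
    if not pp.skip_bandpass:
        od = bandpass(od, pp.filter)
    conc = od_to_concentration(od, mbll)
    ba = block_average(conc, truth.design, pp.block)
    sel = ba.post_mask
    t_post = ba.t_rel_s[sel]
    kernel = hrf_value(t_post, truth.hrf)
    true_curves = {"HbO": truth.hrf.amp_hbo_um * kernel,
                   "HbR": truth.hrf.amp_hbr_um * kernel}
    rows = []
    for k, pair in enumerate(conc.pairs):
        for chrom, col in (("HbO", 2 * k), ("HbR", 2 * k + 1)):
            est = ba.mean[sel, col]
            r, r2 = pearson(est, true_curves[chrom])
            rows.append({"method": method, "pair": f"S{pair[0] + 1}-D{pair[1] + 1}",
                         "chromophore": chrom,
                         "mse": mse(est, true_curves[chrom]), "r": r, "r2": r2,
                         "n_trials": ba.n_used})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    """Method-comparison design: ``n_subjects`` fixed physiology + artifact
    realizations, each paired with ``n_runs / n_subjects`` independent
    stimulus-onset randomizations (the study design: random onsets against a
    fixed contaminated recording)."""

    n_runs: int = 25
    n_subjects: int = 5
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    methods: tuple[str, ...] = METHODS
    pipeline: PipelineParams = field(default_factory=PipelineParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 2:
            raise ValidationError("n_runs must be >= 2 for paired tests")
        if not 1 <= self.n_subjects <= self.n_runs:
            raise ValidationError("need 1 <= n_subjects <= n_runs")
        for m in self.methods:
            if m not in METHODS:
                raise ValidationError(f"unknown method '{m}'")


@dataclass
class BenchmarkResult:
    table: pd.DataFrame  # per run/method/pair/chromophore metrics
    per_run: pd.DataFrame  # averaged over pairs: one row per run/method/chrom
    summary: pd.DataFrame  # mean +/- SD per method/chromophore
    ttests: pd.DataFrame  # paired tests between methods, per chromophore
    failures: list[dict]

    def format_summary(self) -> str:
        lines = ["HRF recovery by correction method (mean +/- SD over runs)"]
        for (method, chrom), row in self.summary.iterrows():
            lines.append(
                f"  {method:8s} {chrom}: MSE = {row['mse_mean']:10.4f} +/- "
                f"{row['mse_sd']:9.4f} uM^2   R^2 = {row['r2_mean']:.3f} +/- "
                f"{row['r2_sd']:.3f}")
        lines.append("Paired t-tests vs no correction (per chromophore):")
        for _, row in self.ttests.iterrows():
            lines.append(
                f"  {row['method_a']:8s} vs {row['method_b']:8s} [{row['chromophore']}] "
                f"{row['metric']}: t = {row['t']:9.3f}, p = {row['p']:.3g}")
        return "\n".join(lines)


def _spawn_run_seed(base_seed: int, i: int, tag: int = 0) -> int:
    # stable, independent per-run seeds below 2**31
    return int(np.random.SeedSequence([base_seed, tag, i]).generate_state(1)[0]
               % (2 ** 31))


def run_benchmark(cfg: BenchmarkConfig) -> BenchmarkResult:
    """Generate ``n_runs`` seeded synthetic runs and score every method.

    Runs are grouped into ``n_subjects`` subjects: within a subject the
    physiology and artifact realization is fixed and only the stimulus
    onsets are redrawn, so paired contrasts between methods see the same
    contamination.  Deterministic given ``cfg.seed``.  A stage failure marks
    the run failed and the benchmark continues.
    """
    tables = []
    failures: list[dict] = []
    for i in range(cfg.n_runs):
        subject = i % cfg.n_subjects
        gen_cfg = replace(cfg.generator,
                          seed=_spawn_run_seed(cfg.seed, subject, tag=1),
                          onset_seed=_spawn_run_seed(cfg.seed, i, tag=2))
        try:
            rec, truth = generate_run(gen_cfg)
            for method in cfg.methods:
                df = process_run(rec, truth, method, cfg.pipeline, cfg.generator.mbll)
                df.insert(0, "run", i)
                tables.append(df)
        except Exception as exc:  # noqa: BLE001 - run-level isolation
            logger.warning("benchmark run %d failed: %s", i, exc)
            failures.append({"run": i, "error": f"{type(exc).__name__}: {exc}"})
    if not tables:
        raise ValidationError("every benchmark run failed")
    table = pd.concat(tables, ignore_index=True)
    per_run = (table.groupby(["run", "method", "chromophore"], as_index=False)
               [["mse", "r", "r2"]].mean())
    summary = (per_run.groupby(["method", "chromophore"])
               .agg(mse_mean=("mse", "mean"), mse_sd=("mse", "std"),
                    r2_mean=("r2", "mean"), r2_sd=("r2", "std")))
    ttests = _method_ttests(per_run, cfg.methods)
    return BenchmarkResult(table=table, per_run=per_run, summary=summary,
                           ttests=ttests, failures=failures)


def _method_ttests(per_run: pd.DataFrame, methods: tuple[str, ...]) -> pd.DataFrame:
    rows = []
    others = [m for m in methods if m != "none"]
    pairs = [(m, "none") for m in others if "none" in methods]
    if "tpca" in methods:
        pairs += [("tpca", m) for m in others if m != "tpca"]
    for chrom in sorted(per_run["chromophore"].unique()):
        sub = per_run[per_run["chromophore"] == chrom]
        wide_mse = sub.pivot(index="run", columns="method", values="mse")
        wide_r2 = sub.pivot(index="run", columns="method", values="r2")
        for a, b in pairs:
            for metric, wide in (("mse", wide_mse), ("r2", wide_r2)):
                t, p = paired_ttest(wide[a].to_numpy(), wide[b].to_numpy())
                rows.append({"method_a": a, "method_b": b, "chromophore": chrom,
                             "metric": metric, "t": t, "p": p})
    return pd.DataFrame(rows)


def summarize(result: BenchmarkResult) -> str:
    return result.format_summary()
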