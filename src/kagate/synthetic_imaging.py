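"""Synthetic two-photon line-scan data and the experimental analysis chain.

Emulates the imaging experiments' raw data structure: paired spine/shaft
two-channel (green Ca-sensitive, red morphological) line-scan fluorescence
at 500 Hz, ten interleaved trials per condition per cell, the seven trial
types, a blue-light photoartifact on uncaging trials, and indicator
saturation plus acquisition noise. The analysis chain mirrors the
experimental one: dG/R normalization, re-expression as a fraction of the
green/red ratio at saturating calcium (dG/Gsat), photoartifact removal by
subtracting uncaging-alone averages, 10-trial averages, 100-ms response
integrals, the inhibition fraction, and exact Wilcoxon matched-pairs
statistics.

The calcium-concentration proxy low-pass filters the model's reporter Ca
current with a 50-ms single-exponential decay; indicator defaults put a
single-bAP transient near 20% of saturation (low-affinity indicator
regime). These defaults are configuration, not measured claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import rankdata

from . import calcium_analysis as ca
from .cable_model import Trace
from .protocols import TrialResult

__all__ = [
    "ImagingConfig",
    "TrialBlock",
    "CellRecording",
    "LineScanDataset",
    "CellAnalysis",
    "WilcoxonResult",
    "PopulationResult",
    "fluorescence_from_ca",
    "ca_concentration",
    "simulate_linescan",
    "generate_dataset",
    "analyze_trials",
    "wilcoxon_exact",
    "wilcoxon_null_alpha",
    "population_study",
]

SITES = ("spine", "shaft")


@dataclass
class ImagingConfig:
    """Indicator, acquisition, and noise parameters.

    Concentrations in uM, fluorescence in arbitrary units, rates in Hz.
    ``ca_per_flux`` maps the low-pass-filtered reporter-current magnitude
    (uA*ms/cm2) to a concentration increment.
    """

    kd: float = 2.3                 # indicator dissociation constant (uM)
    ca_rest: float = 0.05           # resting free Ca (uM)
    ca_per_flux: float = 4e5        # uM per (uA*ms/cm2) of filtered flux
    decay_tau: float = 50.0         # ms, transient decay of the proxy
    g0: float = 100.0               # green at resting Ca
    gsat: float = 600.0             # green at saturating Ca
    red: float = 200.0              # red channel mean
    noise_sd: float = 10.0          # additive noise SD per line sample
    noise_model: str = "gaussian"   # "gaussian" | "poisson"
    line_rate: float = 500.0        # Hz
    n_trials: int = 10              # trials per condition per cell
    artifact_amp: float = 30.0      # photoartifact peak (green units)
    artifact_tau: float = 2.0       # ms
    linear_indicator: bool = False  # replace Hill binding by its slope at 0
    cell_cv: float = 0.2            # lognormal CV of per-cell amplitude

    def __post_init__(self):
        if not (self.gsat > self.g0 > 0):
            raise ValueError("require gsat > g0 > 0")
        if self.red <= 0:
            raise ValueError("red must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.line_rate <= 0 or self.n_trials < 1:
            raise ValueError("invalid acquisition parameters")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def sat_ratio(self) -> float:
        """Calibration constant: green/red ratio at saturating calcium."""
        return self.gsat / self.red


def fluorescence_from_ca(ca_um, cfg: ImagingConfig):
    """Green fluorescence from free calcium via single-site Hill binding.

    G = G0 + (Gsat - G0) * ca / (ca + Kd); monotone and saturating. With
    ``cfg.linear_indicator`` the binding curve is replaced by its slope at
    zero calcium (the Kd -> infinity limit at matched initial slope).
    """
    c = np.clip(np.asarray(ca_um, dtype=float), 0.0, None)
    span = cfg.gsat - cfg.g0
    if cfg.linear_indicator:
        out = cfg.g0 + span * c / cfg.kd
    else:
        out = cfg.g0 + span * c / (c + cfg.kd)
    return out if out.ndim else float(out)


def ca_concentration(trial: TrialResult, site: str, cfg: ImagingConfig,
                     amp_scale: float = 1.0) -> np.ndarray:
    """Free-calcium proxy (uM) on the model time grid for one site.

    The magnitude of the inward reporter current is integrated by a leaky
    integrator with time constant ``cfg.decay_tau`` (single-exponential
    transient decay) and scaled to concentration.
    """
    tr = trial.traces[site]
    flux = np.clip(-np.asarray(tr["ica"], dtype=float), 0.0, None)
    dt = tr.dt
    decay = np.exp(-dt / cfg.decay_tau)
    # start at the steady level of the resting reporter current so that the
    # baseline is flat (the cell has been at rest long before the trial)
    y0 = flux[0] * dt / (1.0 - decay)
    y = lfilter([dt], [1.0, -decay], flux, zi=np.array([decay * y0]))[0]
    return cfg.ca_rest + amp_scale * cfg.ca_per_flux * y


@dataclass
class TrialBlock:
    """All repeated line-scan trials of one type for one cell.

    ``channels[site][channel]`` is an (n_trials, n_samples) array.
    """

    trial_type: str
    light: bool
    t: np.ndarray               # line-scan time base (ms)
    t_test: float               # test-pulse onset (ms)
    uncaging_time: float | None
    channels: dict[str, dict[str, np.ndarray]]

    @property
    def n_trials(self) -> int:
        return next(iter(next(iter(self.channels.values())).values())).shape[0]


@dataclass
class CellRecording:
    """One synthetic cell: a single spine/shaft pair, all trial types."""

    cell_id: int
    amp_scale: float
    blocks: dict[str, TrialBlock]


@dataclass
class LineScanDataset:
    cfg: ImagingConfig
    cells: list[CellRecording]
    master_seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: cell, trial, type, site, channel, time, value."""
        rec = []
        for cell in self.cells:
            for ttype, blk in cell.blocks.items():
                for site, chans in blk.channels.items():
                    for chan, arr in chans.items():
                        for k in range(arr.shape[0]):
                            rec.append(pd.DataFrame({
                                "cell": cell.cell_id,
                                "trial": k,
                                "type": ttype,
                                "site": site,
                                "channel": chan,
                                "time": blk.t,
                                "value": arr[k],
                            }))
        return pd.concat(rec, ignore_index=True)


def _resample_indices(t_model: np.ndarray, line_rate: float) -> np.ndarray:
    dt = t_model[1] - t_model[0]
    t_line = np.arange(0.0, t_model[-1] + 1e-9, 1000.0 / line_rate)
    idx = np.round(t_line / dt).astype(int)
    return idx[idx < len(t_model)]


def simulate_linescan(
    trial: TrialResult,
    cfg: ImagingConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
    amp_scale: float = 1.0,
    inh_scale: float = 1.0,
    sites: Sequence[str] = SITES,
) -> TrialBlock:
    """Generate repeated noisy line-scan trials from one model trial.

    The spine/shaft Ca-concentration proxies are mapped to green
    fluorescence, resampled at the line rate, and overlaid with per-sample
    noise on both channels; uncaging (light) trials additionally carry an
    exponential blue-light photoartifact on the green channel starting at
    the uncaging time. ``inh_scale`` scales the Ca transient of
    IPSP-containing trials (used to inject known effect sizes). Identical
    generator state produces identical output.
    """
    n = cfg.n_trials if n_trials is None else n_trials
    any_site = trial.traces[sites[0]]
    idx = _resample_indices(any_site.t, cfg.line_rate)
    t_line = any_site.t[idx]
    light = trial.spec.has_ipsp
    t_unc = trial.t_test - trial.spec.ipsp_lead if light else None

    scale = amp_scale * (inh_scale if light else 1.0)
    channels: dict[str, dict[str, np.ndarray]] = {}
    for site in sites:
        conc = ca_concentration(trial, site, cfg, amp_scale=scale)
        green = fluorescence_from_ca(conc, cfg)[idx]
        if light:
            artifact = np.where(
                t_line >= t_unc,
                cfg.artifact_amp * np.exp(-np.clip(t_line - t_unc, 0, None)
                                          / cfg.artifact_tau),
                0.0,
            )
            green = green + artifact
        green_trials = np.tile(green, (n, 1))
        red_trials = np.full((n, t_line.size), cfg.red)
        if cfg.noise_model == "poisson":
            green_trials = rng.poisson(np.clip(green_trials, 0, None)).astype(float)
            red_trials = rng.poisson(red_trials).astype(float)
        elif cfg.noise_sd > 0:
            green_trials = green_trials + rng.normal(0, cfg.noise_sd, green_trials.shape)
            red_trials = red_trials + rng.normal(0, cfg.noise_sd, red_trials.shape)
        channels[site] = {"green": green_trials, "red": red_trials}
    return TrialBlock(
        trial_type=trial.spec.trial_type,
        light=light,
        t=t_line,
        t_test=trial.t_test,
        uncaging_time=t_unc,
        channels=channels,
    )


def generate_dataset(
    trial_results: dict[str, TrialResult],
    cfg: ImagingConfig,
    n_cells: int = 10,
    master_seed: int = 0,
    inh_scale: float = 1.0,
) -> LineScanDataset:
    """Synthetic population: ``n_cells`` cells, one spine/shaft pair each.

    Per-cell response amplitudes vary lognormally (CV ``cfg.cell_cv``);
    per-trial noise is independent. Seeds derive deterministically from
    ``master_seed`` via numpy SeedSequence spawning.
    """
    ss = np.random.SeedSequence(master_seed)
    cells = []
    for cell_id, child in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(child)
        sigma = np.sqrt(np.log(1.0 + cfg.cell_cv ** 2))
        amp = float(rng.lognormal(-sigma ** 2 / 2.0, sigma))
        blocks = {
            ttype: simulate_linescan(
                trial, cfg, rng, amp_scale=amp, inh_scale=inh_scale
            )
            for ttype, trial in trial_results.items()
        }
        cells.append(CellRecording(cell_id=cell_id, amp_scale=amp, blocks=blocks))
    return LineScanDataset(cfg=cfg, cells=cells, master_seed=master_seed)


# ---------------------------------------------------------------------------
# Analysis chain
# ---------------------------------------------------------------------------

@dataclass
class CellAnalysis:
    """Per-cell trial-averaged dG/Gsat traces, responses, and fractions."""

    traces: dict[tuple[str, str], Trace]          # (trial type, site) -> trace
    responses: dict[tuple[str, str], ca.CaResponse]
    fractions: dict[tuple[str, str], ca.InhibitionResult]  # (condition, site)


def _dg_over_gsat(block: TrialBlock, site: str, cfg: ImagingConfig) -> np.ndarray:
    """Trial-averaged dG/Gsat trace for one site.

    Per trial: dG/R relative to the pre-event baseline, then re-expressed
    as a fraction of the saturating-Ca green/red ratio.
    """
    green = block.channels[site]["green"]
    red = block.channels[site]["red"]
    first_event = block.uncaging_time if block.uncaging_time is not None else block.t_test
    first_event = min(first_event, block.t_test)
    pre = block.t < first_event - 2.0
    if not np.any(pre):
        raise ValueError("no pre-event baseline samples in line scan")
    r_mean = red.mean(axis=1, keepdims=True)
    baseline = green[:, pre].mean(axis=1, keepdims=True)
    dg_r = (green - baseline) / r_mean
    return (dg_r / cfg.sat_ratio).mean(axis=0)


def analyze_trials(
    cell: CellRecording,
    cfg: ImagingConfig,
    window: float = 100.0,
) -> CellAnalysis:
    """Experimental analysis chain for one cell.

    Light-trial photoartifacts are removed by subtracting the matched
    uncaging-alone average (IPSP for IPSP-bAP, train-IPSP for
    train-IPSP-bAP); train baselines are removed by subtracting the
    train-alone average. Responses are 100-ms integrals from test-pulse
    onset; inhibition fractions follow (dCa_ctl - dCa_inh) / dCa_ctl.
    """
    blocks = cell.blocks
    needed_pairs = {
        "single": ("bAP", "IPSP-bAP", None, "IPSP"),
        "train": ("train-bAP", "train-IPSP-bAP", "train", "train-IPSP"),
    }
    mean: dict[tuple[str, str], np.ndarray] = {}
    for ttype, blk in blocks.items():
        for site in blk.channels:
            mean[(ttype, site)] = _dg_over_gsat(blk, site, cfg)

    traces: dict[tuple[str, str], Trace] = {}
    responses: dict[tuple[str, str], ca.CaResponse] = {}
    fractions: dict[tuple[str, str], ca.InhibitionResult] = {}

    def corrected(ttype: str, baseline_type: str | None, site: str) -> np.ndarray:
        y = mean[(ttype, site)]
        if baseline_type is not None:
            y = y - mean[(baseline_type, site)]
        return y

    for cond, (ctl_t, inh_t, ctl_base, inh_base) in needed_pairs.items():
        if ctl_t not in blocks:
            continue
        if inh_t not in blocks or (inh_base and inh_base not in blocks):
            raise ValueError(
                f"incomplete dataset: condition {cond!r} needs trial types "
                f"{[x for x in (ctl_t, inh_t, ctl_base, inh_base) if x]}"
            )
        blk = blocks[ctl_t]
        for site in blk.channels:
            y_ctl = corrected(ctl_t, ctl_base, site)
            y_inh = corrected(inh_t, inh_base, site)
            tr_ctl = Trace(blk.t, {"f": y_ctl})
            tr_inh = Trace(blocks[inh_t].t, {"f": y_inh})
            traces[(ctl_t, site)] = tr_ctl
            traces[(inh_t, site)] = tr_inh
            r_ctl = ca.ca_flux_integral(
                tr_ctl, t0=blk.t_test, window=window, series="f",
                mode="signed", site=site,
            )
            r_inh = ca.ca_flux_integral(
                tr_inh, t0=blocks[inh_t].t_test, window=window, series="f",
                mode="signed", site=site,
            )
            responses[(ctl_t, site)] = r_ctl
            responses[(inh_t, site)] = r_inh
            fractions[(cond, site)] = ca.inhibition_fraction(r_ctl, r_inh)
    return CellAnalysis(traces=traces, responses=responses, fractions=fractions)


# ---------------------------------------------------------------------------
# Exact Wilcoxon matched-pairs signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float        # W+ = sum of ranks of positive differences
    p_value: float          # exact two-sided
    n_used: int             # pairs remaining after dropping zero differences
    degenerate: bool = False


def _signed_rank_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Probability mass of W+ (on the doubled-rank integer grid) under the
    null that each signed rank is positive with probability 1/2."""
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_exact(pairs_or_diffs, second: Sequence[float] | None = None) -> WilcoxonResult:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Accepts paired samples ``(x, y)`` (differences x - y) or a single array
    of differences. Zero differences are dropped before ranking; ties get
    average ranks. The p-value is computed from the full distribution of
    the positive-rank sum over all sign assignments (equivalently, by
    enumeration of the 2^n patterns), doubled for two-sidedness and capped
    at 1. All-zero differences give p = 1 with a degeneracy flag.
    """
    if second is not None:
        d = np.asarray(pairs_or_diffs, dtype=float) - np.asarray(second, dtype=float)
    else:
        d = np.asarray(pairs_or_diffs, dtype=float)
    if d.size < 1:
        raise ValueError("at least one pair is required")
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, degenerate=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    double_ranks = np.round(2.0 * ranks).astype(int)
    pmf = _signed_rank_distribution(double_ranks)
    w2 = int(round(2.0 * w_plus))
    p_le = float(pmf[: w2 + 1].sum())
    p_ge = float(pmf[w2:].sum())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonResult(statistic=w_plus, p_value=p, n_used=n)


def wilcoxon_null_alpha(n: int, level: float = 0.05) -> float:
    """Attainable type-I error P(p < level) of the exact test at sample
    size ``n`` with continuous (tie-free, zero-free) differences."""
    ranks = np.arange(1, n + 1, dtype=float)
    pmf = _signed_rank_distribution((2 * ranks).astype(int))
    alpha = 0.0
    for w2, prob in enumerate(pmf):
        if prob == 0.0:
            continue
        p_le = pmf[: w2 + 1].sum()
        p_ge = pmf[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        if p < level:
            alpha += prob
    return float(alpha)


# ---------------------------------------------------------------------------
# Population study
# ---------------------------------------------------------------------------

@dataclass
class PopulationResult:
    table: pd.DataFrame
    tests: dict[str, WilcoxonResult]
    master_seed: int
    condition_labels: tuple[str, str]


def population_study(
    trial_results: dict[str, TrialResult],
    cfg: ImagingConfig | None = None,
    n_cells: int = 10,
    master_seed: int = 0,
    inh_scale_b: float = 1.0,
    condition_labels: tuple[str, str] = ("A", "B"),
) -> PopulationResult:
    """Paired two-condition population experiment on synthetic cells.

    Each cell contributes a spine and a shaft inhibition fraction in two
    conditions sharing the cell's response amplitude but with independent
    noise; condition B scales the inhibited-trial Ca transient by
    ``inh_scale_b`` (1.0 = null effect). Per-site paired differences are
    tested with the exact Wilcoxon signed-rank test. Fully reproducible
    from ``master_seed``.
    """
    if n_cells < 2:
        raise ValueError("population study requires n_cells >= 2")
    cfg = cfg or ImagingConfig()
    ss = np.random.SeedSequence(master_seed)
    rows = []
    for cell_id, child in enumerate(ss.spawn(n_cells)):
        rng = np.random.default_rng(child)
        sigma = np.sqrt(np.log(1.0 + cfg.cell_cv ** 2))
        amp = float(rng.lognormal(-sigma ** 2 / 2.0, sigma))
        fracs = {}
        peaks = {}
        for label, inh_scale in zip(condition_labels, (1.0, inh_scale_b)):
            blocks = {
                ttype: simulate_linescan(trial, cfg, rng, amp_scale=amp,
                                         inh_scale=inh_scale)
                for ttype, trial in trial_results.items()
            }
            cell = CellRecording(cell_id=cell_id, amp_scale=amp, blocks=blocks)
            res = analyze_trials(cell, cfg)
            for (cond, site), fr in res.fractions.items():
                if cond == "single":
                    fracs[(label, site)] = fr.fraction
            for (ttype, site), tr in res.traces.items():
                if ttype == "bAP":
                    peaks[(label, site)] = float(np.max(tr["f"]))
        for site in SITES:
            rows.append({
                "cell": cell_id,
                "site": site,
                f"fraction_{condition_labels[0]}": fracs[(condition_labels[0], site)],
                f"fraction_{condition_labels[1]}": fracs[(condition_labels[1], site)],
                f"peak_{condition_labels[0]}": peaks[(condition_labels[0], site)],
                f"peak_{condition_labels[1]}": peaks[(condition_labels[1], site)],
            })
    table = pd.DataFrame(rows)
    tests = {}
    for site in SITES:
        sub = table[table["site"] == site]
        tests[site] = wilcoxon_exact(
            sub[f"fraction_{condition_labels[1]}"].to_numpy(),
            sub[f"fraction_{condition_labels[0]}"].to_numpy(),
        )
    return PopulationResult(
        table=table, tests=tests, master_seed=master_seed,
        condition_labels=condition_labels,
    )
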