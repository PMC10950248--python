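"""Response analysis: rheobase, dVf/hVf classification, effective weights, statistics.

The chain mirrors how perturbation responses are quantified in the
visual-flow literature: for every neuron the *total input current*
I = I_in + I_noise + I_rec + sum_m I_m is baselined over the 500 ms before
the perturbation and averaged over the analyzed trials and the 1000 ms
perturbation window; the response DeltaI is compared against +/- 0.05 of
the cell's rheobase to label it depolarized-with-visual-flow (dVf),
hyperpolarized (hVf) or unclassified.  Sweep-level labels (perturbation
sensitive vs direction selective), time-windowed effective synaptic
weights, firing-rate smoothing and the ANOVA-gated Welch test protocol
complete the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glif import DT_MS, GLIFParams
from .simulator import single_neuron_response

__all__ = [
    "rheobase",
    "baseline_current",
    "delta_current",
    "classify",
    "smooth_firing_rate",
    "effective_weight_pair",
    "effective_weight_type",
    "classify_across_directions",
    "preferred_frequency",
    "compare_classes",
    "confusion_matrix",
    "ResponseSummary",
]

LABELS = ("dVf", "hVf", "unclassified")
CLASSIFICATION_FACTOR = 0.05


class NonExcitableError(RuntimeError):
    """No spike was elicited below the configured current ceiling."""


@dataclass
class ResponseSummary:
    """Per-neuron response table plus the thresholds used to label it."""

    table: pd.DataFrame  # id, I0, dI, dI_in, dI_noise, dI_rec, dI_asc, theta_rheo, label
    factor: float = CLASSIFICATION_FACTOR


# ---------------------------------------------------------------------------
# rheobase


def rheobase(
    params: GLIFParams,
    start: float = 1.0,
    increment: float = 0.01,
    pulse_ms: float = 1000.0,
    ceiling: float = 2000.0,
    dt: float = DT_MS,
) -> float:
    """Smallest grid current (start + k*increment) that elicits a spike.

    A rectangular pulse of ``pulse_ms`` is injected into the resting cell;
    the cell state is reset between pulses, so whether a pulse elicits a
    spike is monotone in its amplitude and the linear scan of the grid can
    be carried out as a bisection over the same grid with an identical
    result.
    """
    if increment <= 0 or pulse_ms <= 0:
        raise ValueError("increment and pulse duration must be positive")
    n_steps = int(round(pulse_ms / dt))

    def fires(i_amp: float) -> bool:
        _, spikes = single_neuron_response(params, np.full(n_steps, i_amp), dt=dt)
        return len(spikes) > 0

    if fires(start):
        return start
    n_grid = int(np.ceil((ceiling - start) / increment))
    if not fires(start + n_grid * increment):
        raise NonExcitableError(
            f"no spike below ceiling {ceiling} pA (v_th={params.v_th}, E_L={params.E_L})"
        )
    lo, hi = 0, n_grid  # fires(start + lo*inc) False, fires(start + hi*inc) True
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fires(start + mid * increment):
            hi = mid
        else:
            lo = mid
    return start + hi * increment


# ---------------------------------------------------------------------------
# currents


def baseline_current(traces: np.ndarray, window: tuple[int, int] = (0, 500)) -> np.ndarray:
    """Mean total current over the pre-onset window, averaged across trials.

    ``traces``: (n_trials, n_steps, ...) or (n_steps, ...) total-current
    arrays; the window is half-open in steps.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :, None]
    elif traces.ndim == 2:
        traces = traces[None, :, :]
    a, b = window
    if b > traces.shape[1] or a < 0 or a >= b:
        raise ValueError(f"baseline window {window} outside trace of {traces.shape[1]} steps")
    return traces[:, a:b].mean(axis=(0, 1))


def delta_current(
    window_components: np.ndarray,
    i0: np.ndarray,
) -> pd.DataFrame:
    """Trial-averaged visual-flow response with per-source decomposition.

    ``window_components``: (n_trials, n_neurons, 4) mean currents over the
    perturbation window in source order (in, noise, rec, asc).  Returns a
    frame with dI = <I_in> + <I_noise> + <I_rec> + <sum I_m> - I0 and the
    retained components.
    """
    comp = np.asarray(window_components, dtype=float)
    if comp.ndim == 2:
        comp = comp[None]
    if comp.shape[-1] != 4:
        raise ValueError("expected four source components (in, noise, rec, asc)")
    i0 = np.asarray(i0, dtype=float)
    if i0.shape[0] != comp.shape[1]:
        raise ValueError("trial/neuron count mismatch between components and baseline")
    mean = comp.mean(axis=0)
    total = mean.sum(axis=1)
    return pd.DataFrame(
        {
            "dI": total - i0,
            "dI_in": mean[:, 0],
            "dI_noise": mean[:, 1],
            "dI_rec": mean[:, 2],
            "dI_asc": mean[:, 3],
            "I0": i0,
        }
    )


def classify(d_i, theta_rheo, factor: float = CLASSIFICATION_FACTOR):
    """Label responses: dVf above +factor*rheobase, hVf below -factor*rheobase.

    Strict inequalities -- a response exactly on a threshold stays
    unclassified.  Accepts scalars or arrays; returns str or object array.
    """
    d_i = np.asarray(d_i, dtype=float)
    th = factor * np.asarray(theta_rheo, dtype=float)
    if np.any(~np.isfinite(d_i)):
        raise ValueError("non-finite response values")
    if np.any(np.asarray(theta_rheo) <= 0):
        raise ValueError("rheobase must be positive")
    out = np.where(d_i > th, "dVf", np.where(d_i < -th, "hVf", "unclassified"))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# firing rates


def smooth_firing_rate(
    spike_times_ms: np.ndarray,
    T_ms: float,
    sample_hz: float = 60.0,
    kernel_ms: float = 150.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned instantaneous rate at ``sample_hz`` smoothed by a Gaussian kernel.

    The 150 ms filter width is interpreted as the kernel standard
    deviation, truncated at +/- 3 sigma and normalized to unit sum so the
    total spike count is preserved up to edge truncation.  Returns
    ``(t_ms, rate_hz)``.
    """
    bin_ms = 1000.0 / sample_hz
    n_bins = int(np.ceil(T_ms / bin_ms))
    counts, edges = np.histogram(
        np.asarray(spike_times_ms, dtype=float), bins=n_bins, range=(0.0, n_bins * bin_ms)
    )
    rate = counts / (bin_ms / 1000.0)
    sigma_bins = kernel_ms / bin_ms
    half = int(np.ceil(3.0 * sigma_bins))
    x = np.arange(-half, half + 1)
    kern = np.exp(-0.5 * (x / sigma_bins) ** 2)
    kern /= kern.sum()
    smoothed = np.convolve(rate, kern, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, smoothed


# ---------------------------------------------------------------------------
# effective synaptic weights


def effective_weight_pair(weight: float, spike_indicator: np.ndarray, dt_steps: int | None = None) -> float:
    """Time-windowed effective weight of one synapse: (1/Dt) sum_t W x(t)."""
    x = np.asarray(spike_indicator)
    n = len(x) if dt_steps is None else int(dt_steps)
    if n <= 0:
        raise ValueError("window length must be positive")
    return float(weight) * float(np.sum(x)) / n


def effective_weight_type(pair_values) -> float:
    """Aggregate effective weight of a presynaptic type: sum over its members."""
    return float(np.sum(pair_values))


def effective_weight_table(
    recurrent: pd.DataFrame,
    neurons: pd.DataFrame,
    spike_counts: np.ndarray,
    window_steps: int,
) -> pd.DataFrame:
    """Per (presynaptic type -> target neuron) effective weights for one window.

    ``spike_counts``: per-neuron spike counts inside the window (already
    summed over the window; trial averaging is the caller's business).
    Equivalent to summing effective_weight_pair over every synapse, grouped
    by the presynaptic neuron's type.
    """
    if window_steps <= 0:
        raise ValueError("window length must be positive")
    pre = recurrent["pre"].to_numpy()
    post = recurrent["post"].to_numpy()
    w = recurrent["weight"].to_numpy()
    counts = np.asarray(spike_counts, dtype=float)
    contrib = w * counts[pre] / window_steps
    frame = pd.DataFrame(
        {
            "pre_type": neurons["type"].to_numpy()[pre],
            "post": post,
            "w_eff": contrib,
        }
    )
    return frame.groupby(["pre_type", "post"], as_index=False)["w_eff"].sum()


# ---------------------------------------------------------------------------
# sweep-level classification


def classify_across_directions(labels_per_direction) -> str:
    """Collapse one label per drift direction into a sweep-level category.

    All-dVf (resp. all-hVf) across every direction marks a perturbation
    sensitive neuron; a single responsive direction with unclassified
    behavior elsewhere marks a direction-selective one; anything else is
    'other'.
    """
    labels = list(labels_per_direction)
    if len(labels) != 8:
        raise ValueError(f"expected one label per direction (8), got {len(labels)}")
    if any(l not in LABELS for l in labels):
        raise ValueError(f"unknown label among {labels}")
    if all(l == "dVf" for l in labels):
        return "perturbation-sensitive dVf"
    if all(l == "hVf" for l in labels):
        return "perturbation-sensitive hVf"
    responsive = [l for l in labels if l != "unclassified"]
    if len(responsive) == 1:
        return f"direction-selective {responsive[0]}"
    return "other"


def preferred_frequency(d_i_per_tf: np.ndarray, label: str, tfs=None) -> float:
    """Preferred drift frequency: argmax of DeltaI for dVf, argmin for hVf.

    Ties break toward the lower frequency.
    """
    d_i = np.asarray(d_i_per_tf, dtype=float)
    tfs = np.arange(1, len(d_i) + 1, dtype=float) if tfs is None else np.asarray(tfs, dtype=float)
    if label == "dVf":
        return float(tfs[int(np.argmax(d_i))])
    if label == "hVf":
        return float(tfs[int(np.argmin(d_i))])
    raise ValueError("preferred frequency is defined for dVf/hVf neurons only")


# ---------------------------------------------------------------------------
# statistics protocol


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


def compare_classes(values, labels, gate_p: float = 0.01) -> dict:
    """ANOVA-gated pairwise Welch tests between labeled groups.

    With more than two groups a one-way ANOVA is run first and pairwise
    two-sided Welch t-tests follow only if it is significant at
    ``gate_p``; with exactly two groups the Welch test runs directly.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for lab in pd.unique(labels):
        v = values[labels == lab]
        if len(v) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
        groups[lab] = v
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    report: dict = {"groups": {k: {"n": len(v), "mean": float(v.mean())} for k, v in groups.items()}}
    if len(names) == 2:
        report["anova_p"] = None
        gate_open = True
    else:
        f, p = sps.f_oneway(*groups.values())
        report["anova_F"], report["anova_p"] = float(f), float(p)
        gate_open = p < gate_p
    report["pairwise"] = []
    if gate_open:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                t, p = sps.ttest_ind(groups[names[i]], groups[names[j]], equal_var=False)
                report["pairwise"].append(
                    {
                        "a": str(names[i]),
                        "b": str(names[j]),
                        "t": float(t),
                        "p": float(p),
                        "stars": _stars(float(p)),
                    }
                )
    return report


def confusion_matrix(labels_ref, labels_new, classes=LABELS) -> pd.DataFrame:
    """Row-normalized fractions of reference classes mapped to new classes."""
    ref = np.asarray(labels_ref)
    new = np.asarray(labels_new)
    if ref.shape != new.shape:
        raise ValueError("label vectors must have identical length")
    mat = pd.DataFrame(0.0, index=list(classes), columns=list(classes))
    for r in classes:
        sel = ref == r
        n = int(sel.sum())
        if n == 0:
            mat.loc[r] = np.nan
            continue
        for c in classes:
            mat.loc[r, c] = float(np.sum(sel & (new == c))) / n
    return mat
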