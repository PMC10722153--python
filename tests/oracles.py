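"""Independent oracles used by the tests.

Each oracle recomputes a quantity through a different route than the
package (direct quadratic programming, step-up enumeration, incomplete-beta
closed form, fine-grid numerical convolution) so that agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import betainc

from graspmvpa.design import MEASURED_PHASES


def svm_primal_qp(X: np.ndarray, y: np.ndarray, C: float = 1.0):
    """Soft-margin linear SVM solved as an explicit slack-variable QP.

    Minimizes 0.5*||w||^2 + C*sum(xi) subject to y_i (w.x_i + b) >= 1 - xi_i,
    xi >= 0, with a generic constrained optimizer (no SMO, no libsvm).
    ``y`` must be +/-1.  Returns (w, b).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, d = X.shape

    def objective(z):
        w = z[:d]
        xi = z[d + 1:]
        return 0.5 * float(w @ w) + C * float(xi.sum())

    constraints = [
        {"type": "ineq",
         "fun": (lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1.0 + z[d + 1 + i])}
        for i in range(n)
    ]
    bounds = [(None, None)] * (d + 1) + [(0.0, None)] * n
    z0 = np.zeros(d + 1 + n)
    z0[d + 1:] = 1.0
    res = minimize(objective, z0, method="SLSQP", bounds=bounds,
                   constraints=constraints,
                   options={"maxiter": 1000, "ftol": 1e-12})
    assert res.success, res.message
    return res.x[:d], float(res.x[d])


def bh_stepup(p_values, q: float):
    """Benjamini-Hochberg by literal step-up enumeration.

    Finds the largest rank i with p_(i) <= i*q/m and rejects every p-value
    at or below that order statistic.
    """
    p = np.asarray(p_values, float)
    m = p.size
    order = np.sort(p)
    k = 0
    for i in range(1, m + 1):
        if order[i - 1] <= i * q / m:
            k = i
    if k == 0:
        return np.zeros(m, dtype=bool)
    return p <= order[k - 1]


def t_two_tailed_p(t: float, df: int) -> float:
    """Two-tailed Student-t p-value via the regularized incomplete beta:
    P(|T| > t) = I_{df/(df+t^2)}(df/2, 1/2)."""
    return float(betainc(df / 2.0, 0.5, df / (df + t * t)))


# ---------------------------------------------------------------------------
# Fine-grid convolution oracle for the simulator / percent signal change
# ---------------------------------------------------------------------------

def _gamma_pdf(t: np.ndarray, shape: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = t[pos] ** (shape - 1.0) * np.exp(-t[pos]) / math.gamma(shape)
    return out


def hrf_oracle(t: np.ndarray) -> np.ndarray:
    """Unit-peak double gamma (peak shape 6, undershoot shape 16, ratio 6),
    written directly from the gamma density."""
    h = _gamma_pdf(t, 6.0) - _gamma_pdf(t, 16.0) / 6.0
    return h / h.max()


def event_response_oracle(duration: float, dt: float = 0.01, span: float = 40.0):
    """Unit-peak response to a ``duration``-second boxcar, by direct
    numerical convolution on a fine grid."""
    t = np.arange(0.0, span, dt)
    box = (t < duration).astype(float)
    conv = np.convolve(box, hrf_oracle(t))[: t.size] * dt
    return t, conv / conv.max()


def universal_timecourse_oracle(design, events, universal_amp: float) -> np.ndarray:
    """Expected noise-free relative signal (1 + evoked/100) on the volume grid."""
    vol_t = np.arange(design.volumes_per_run) * design.tr_seconds
    u = np.zeros_like(vol_t)
    for ev in events:
        for phase in MEASURED_PHASES:
            tg, shape = event_response_oracle(design.phase_durations_seconds[phase])
            u += universal_amp * np.interp(vol_t - ev.phase_onsets_seconds[phase],
                                           tg, shape, left=0.0, right=0.0)
    return 1.0 + u / 100.0


def psc_oracle(design, events, phase: str, universal_amp: float,
               lag_volumes: int = 3) -> float:
    """Expected percent signal change, recomputed from first principles:
    fine-grid convolution, the lead-in + last-ITI-volume baseline, and the
    3-volume lagged window rule."""
    rel = universal_timecourse_oracle(design, events, universal_amp)
    base_idx = list(range(design.lead_in_volumes))
    iti_dur = design.phase_durations_seconds["iti"]
    for ev in events:
        last = int(math.floor((ev.phase_onsets_seconds["iti"] + iti_dur)
                              / design.tr_seconds)) - 1
        if 0 <= last < design.volumes_per_run:
            base_idx.append(last)
    base = rel[sorted(set(base_idx))].mean()
    window_means = []
    for ev in events:
        v = int(math.floor(ev.phase_onsets_seconds[phase] / design.tr_seconds))
        w = np.arange(v + lag_volumes, v + lag_volumes + 3)
        if w[-1] < design.volumes_per_run:
            window_means.append(rel[w].mean())
    return 100.0 * (np.mean(window_means) - base) / base
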