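"""Two-state (P1/P2) hidden Markov kernel over a marker chromosome.

The chain's hidden state is the parental origin at each marker; the
transition probability across interval ``m`` is the recombination fraction
``r[m]``, and observed calls are miscalled with symmetric probability ``e``
(HET and MISSING observations are uninformative). Everything is vectorized
across segregants; arrays are time-major ``(M, n, 2)``.

Used by genotype imputation (posterior decoding at fixed r) and by genetic
map estimation (EM updates of r from expected switch counts).
"""

from __future__ import annotations

import numpy as np

from .core import P1, P2


def _emission_column(obs_col: np.ndarray, e: float) -> tuple[np.ndarray, np.ndarray]:
    """P(observation | state) for one marker; uninformative obs -> 1."""
    is0 = obs_col == P1
    is1 = obs_col == P2
    b0 = np.where(is0, 1.0 - e, np.where(is1, e, 1.0))
    b1 = np.where(is1, 1.0 - e, np.where(is0, e, 1.0))
    return b0, b1


def _forward(obs: np.ndarray, r: np.ndarray, e: float):
    """Scaled forward pass. Returns (alpha, scale, loglik-per-segregant)."""
    n, m_markers = obs.shape
    alpha = np.empty((m_markers, n, 2))
    scale = np.empty((m_markers, n))
    b0, b1 = _emission_column(obs[:, 0], e)
    a0, a1 = 0.5 * b0, 0.5 * b1
    c = a0 + a1
    alpha[0, :, 0], alpha[0, :, 1] = a0 / c, a1 / c
    scale[0] = c
    for m in range(1, m_markers):
        rm = r[m - 1]
        p0 = alpha[m - 1, :, 0] * (1.0 - rm) + alpha[m - 1, :, 1] * rm
        p1 = alpha[m - 1, :, 0] * rm + alpha[m - 1, :, 1] * (1.0 - rm)
        b0, b1 = _emission_column(obs[:, m], e)
        a0, a1 = p0 * b0, p1 * b1
        c = a0 + a1
        alpha[m, :, 0], alpha[m, :, 1] = a0 / c, a1 / c
        scale[m] = c
    return alpha, scale, np.log(scale).sum(axis=0)


def posterior(obs: np.ndarray, r: np.ndarray, e: float) -> np.ndarray:
    """Smoothed state posteriors, shape (n, M, 2)."""
    n, m_markers = obs.shape
    alpha, scale, _ = _forward(obs, r, e)
    gamma = np.empty((m_markers, n, 2))
    beta0 = np.ones(n)
    beta1 = np.ones(n)
    gamma[-1, :, 0] = alpha[-1, :, 0]
    gamma[-1, :, 1] = alpha[-1, :, 1]
    for m in range(m_markers - 2, -1, -1):
        rm = r[m]
        b0, b1 = _emission_column(obs[:, m + 1], e)
        t0 = b0 * beta0
        t1 = b1 * beta1
        c = scale[m + 1]
        beta0, beta1 = ((1.0 - rm) * t0 + rm * t1) / c, (rm * t0 + (1.0 - rm) * t1) / c
        g0 = alpha[m, :, 0] * beta0
        g1 = alpha[m, :, 1] * beta1
        tot = g0 + g1
        gamma[m, :, 0], gamma[m, :, 1] = g0 / tot, g1 / tot
    return gamma.transpose(1, 0, 2)


def expected_switches(obs: np.ndarray, r: np.ndarray, e: float):
    """E-step sufficient statistics for the per-interval recombination
    fractions: (sum over segregants of P(state change at interval m),
    total log-likelihood)."""
    n, m_markers = obs.shape
    alpha, scale, loglik = _forward(obs, r, e)
    xi_diff = np.zeros(m_markers - 1)
    beta0 = np.ones(n)
    beta1 = np.ones(n)
    for m in range(m_markers - 2, -1, -1):
        rm = r[m]
        b0, b1 = _emission_column(obs[:, m + 1], e)
        t0 = b0 * beta0
        t1 = b1 * beta1
        # xi[s, s'] ∝ alpha[m, s] T[s, s'] B[m+1, s'] beta[m+1, s']; the
        # scaled quantities below already sum to 1 over (s, s')
        c = scale[m + 1]
        x01 = alpha[m, :, 0] * rm * t1 / c
        x10 = alpha[m, :, 1] * rm * t0 / c
        xi_diff[m] = (x01 + x10).sum()
        beta0, beta1 = ((1.0 - rm) * t0 + rm * t1) / c, (rm * t0 + (1.0 - rm) * t1) / c
    return xi_diff, float(loglik.sum())
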