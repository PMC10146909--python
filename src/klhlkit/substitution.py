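"""Embedded JTT amino-acid substitution model.

The Jones–Taylor–Thornton (1992) empirical model is used both for
maximum-likelihood pairwise distance estimation (:mod:`klhlkit.phylo`) and as
the substitution kernel of the family simulator (:mod:`klhlkit.synthetic_data`),
so distances estimated on simulated alignments are model-consistent with the
generating process.

The model is a general time-reversible rate matrix ``Q = S @ diag(pi)`` built
from the published exchangeability table ``S`` and equilibrium frequencies
``pi``, normalised so that the expected number of substitutions per site per
unit time at equilibrium is one (``-sum_i pi_i * Q_ii == 1``).  Transition
probabilities ``P(t) = expm(Q t)`` are evaluated through a one-time symmetric
eigendecomposition, which makes the many evaluations needed by distance
optimisation and bootstrapping cheap.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize_scalar

#: Amino-acid ordering of the model matrices (the conventional PAML order).
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Published JTT exchangeabilities, lower triangle, rows R..V against columns
# A..Y in the AA_ORDER above.
_JTT_LOWER = [
    [58],
    [54, 45],
    [81, 16, 528],
    [56, 113, 34, 10],
    [57, 310, 86, 49, 9],
    [105, 29, 58, 767, 5, 323],
    [179, 137, 81, 130, 59, 26, 119],
    [27, 328, 391, 112, 69, 597, 26, 23],
    [36, 22, 47, 11, 17, 9, 12, 6, 16],
    [30, 38, 12, 7, 23, 72, 9, 6, 56, 229],
    [35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14],
    [54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65],
    [15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43],
    [194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17],
    [378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285],
    [475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477],
    [9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12],
    [11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71],
    [298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16],
]

#: JTT equilibrium amino-acid frequencies (same ordering as :data:`AA_ORDER`).
JTT_FREQS = np.array(
    [0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
     0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
     0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005]
)
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()


def _build_rate_matrix() -> np.ndarray:
    s = np.zeros((20, 20))
    for i, row in enumerate(_JTT_LOWER, start=1):
        for j, v in enumerate(row):
            s[i, j] = s[j, i] = float(v)
    q = s * JTT_FREQS[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # scale to one expected substitution per site per unit time
    scale = -(JTT_FREQS * np.diag(q)).sum()
    return q / scale


#: Normalised JTT rate matrix (rows sum to zero; -sum(pi_i Q_ii) == 1).
JTT_RATE_MATRIX = _build_rate_matrix()


def _eigensystem():
    """Symmetric eigendecomposition of Q, exploiting time reversibility."""
    pi = JTT_FREQS
    d = np.sqrt(pi)
    b = (JTT_RATE_MATRIX * d[:, None]) / d[None, :]
    b = 0.5 * (b + b.T)  # clean up round-off asymmetry
    lam, u = np.linalg.eigh(b)
    left = u.T * d[None, :]        # U^T D^{1/2}
    right = (u.T / d[None, :]).T   # D^{-1/2} U
    return lam, right, left


_LAM, _RIGHT, _LEFT = _eigensystem()


def transition_matrix(t: float) -> np.ndarray:
    """Transition probability matrix ``P(t) = expm(Q t)``.

    Parameters
    ----------
    t : float
        Evolutionary time in expected substitutions per site (``t >= 0``).
    """
    if t < 0:
        raise ValueError("evolutionary time must be non-negative")
    p = (_RIGHT * np.exp(_LAM * t)[None, :]) @ _LEFT
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def encode(seq: str) -> np.ndarray:
    """Encode residues as model indices; gaps/unknowns become -1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.int64)


def pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 matrix of aligned residue-pair counts under pairwise deletion.

    Sites where either row is a gap or an ambiguous residue (encoded -1)
    are excluded.
    """
    if a.shape != b.shape:
        raise ValueError("rows must have identical length")
    ok = (a >= 0) & (b >= 0)
    pairs = a[ok] * 20 + b[ok]
    return np.bincount(pairs, minlength=400).reshape(20, 20).astype(float)


def log_likelihood(counts: np.ndarray, t: float) -> float:
    """Log-likelihood of a pair-count matrix at divergence time ``t``.

    ``ll(t) = sum_ab N_ab * log(pi_a * P_ab(t))``.
    """
    p = transition_matrix(t)
    joint = JTT_FREQS[:, None] * p
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lp = np.log(joint[mask])
    if np.any(np.isneginf(lp)):
        return -np.inf
    return float((counts[mask] * lp).sum())


def ml_distance(counts: np.ndarray, t_max: float = 10.0, tol: float = 1e-6) -> float:
    """Maximum-likelihood JTT distance for a pair-count matrix.

    Maximises the log-likelihood over ``t in [1e-8, t_max]`` with a bounded
    derivative-free search.  Identical sequences return exactly 0.0; pairs
    whose optimum sits at the boundary are reported as saturated at ``t_max``
    with a warning.

    Raises
    ------
    ValueError
        If the count matrix contains no comparable sites.
    """
    total = counts.sum()
    if total == 0:
        raise ValueError("no shared sites")
    if counts.sum() == np.trace(counts):
        return 0.0
    res = minimize_scalar(
        lambda t: -log_likelihood(counts, t),
        bounds=(1e-8, t_max),
        method="bounded",
        options={"xatol": tol},
    )
    t_hat = float(res.x)
    if t_hat >= t_max - 10 * tol:
        warnings.warn(
            f"pairwise distance saturated; reporting t_max={t_max}", stacklevel=2
        )
        return t_max
    return t_hat
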