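"""Self-contained verification computations over synthetic inputs.

Each function here recomputes, from scratch, one of the package's headline
properties — metric sanity, the exact-algebra equivalences between the
propagation formulations, the labeling-regime contrast between plain
propagation and fitted short-walk weights, weight-sign recovery, and walk
mixing.  They back both the test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from .evaluation import CVProtocol, auroc, cross_validate, slp_lambda_sweep
from .graph import normalize_asymmetric, normalize_symmetric
from .model import fit_weights, score_nprop
from .propagation import glp_exact, glp_truncated, slp_via_alp
from .synthetic import default_spec, generate
from .diagnostics import mixing_report, stationary_distribution

__all__ = [
    "random_classifier_auroc", "perfect_classifier_auroc",
    "slp_alp_equivalence", "series_solver_equivalence",
    "nprop_glp_identity", "regime_contrast", "weight_sign_recovery",
    "mixing_diagnostics",
]


def _random_graphs(seed: int, n_graphs: int = 20, n_range=(50, 200)):
    """Connected Erdős–Rényi graphs with a handful of positives each."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_graphs):
        n = int(rng.integers(*n_range))
        spec = default_spec("assortative", seed=int(rng.integers(2**31 - 1)),
                            n=n, n_pos=max(5, n // 10))
        G, y = generate(spec)
        out.append((G, y))
    return out


def random_classifier_auroc(seed: int, n: int = 10_000, n_pos: int = 500,
                            n_reps: int = 200) -> float:
    """Mean AUROC of label-independent scores; should sit at 0.5."""
    rng = np.random.default_rng(seed)
    labels = np.r_[np.ones(n_pos), np.zeros(n - n_pos)]
    vals = [auroc(rng.normal(size=n), labels) for _ in range(n_reps)]
    return float(np.mean(vals))


def perfect_classifier_auroc(seed: int, n: int = 1000, n_pos: int = 50) -> float:
    """AUROC of any scoring that puts all positives above all negatives."""
    rng = np.random.default_rng(seed)
    labels = np.zeros(n)
    labels[rng.choice(n, n_pos, replace=False)] = 1
    scores = np.where(labels == 1, 1.0 + rng.random(n), rng.random(n))
    return float(auroc(scores, labels))


def slp_alp_equivalence(seed: int, lam: float = 0.5) -> float:
    """Max |direct SLP - SLP-via-ALP| over 20 random graphs."""
    worst = 0.0
    for G, y in _random_graphs(seed):
        direct = glp_exact(normalize_symmetric(G), y, lam, tol=1e-10)
        via = slp_via_alp(normalize_asymmetric(G), y, lam, tol=1e-10)
        worst = max(worst, float(np.abs(direct - via).max()))
    return worst


def series_solver_equivalence(seed: int, R: int = 500) -> float:
    """Max |truncated series at R - exact solve| over graphs and lambdas."""
    worst = 0.0
    for G, y in _random_graphs(seed):
        S = normalize_symmetric(G)
        for lam in (0.1, 0.5, 0.9):
            diff = np.abs(glp_truncated(S, y, lam, R)
                          - glp_exact(S, y, lam, tol=1e-12)).max()
            worst = max(worst, float(diff))
    return worst


def nprop_glp_identity(seed: int, lam: float = 0.45) -> float:
    """Max |(NProp with geometric weights + y) - truncated GLP at R=3|."""
    worst = 0.0
    for G, y in _random_graphs(seed):
        S = normalize_symmetric(G)
        f = score_nprop(S, y, np.array([lam, lam**2, lam**3])) + y
        worst = max(worst, float(np.abs(f - glp_truncated(S, y, lam, 3)).max()))
    return worst


def regime_contrast(seed: int, n_seeds: int = 20) -> dict:
    """Mean test AUROC of best-lambda SLP and fitted 3Prop per regime.

    Propagation gets its most favourable lambda (max over the grid of the
    per-lambda mean held-out AUROC); 3Prop runs the nested CV protocol.
    """
    out = {}
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    for pattern in ("shared_neighbor", "assortative"):
        slp_profiles, tp = [], []
        for s in seeds:
            G, y = generate(default_spec(pattern, seed=int(s)))
            sweep = slp_lambda_sweep(G, y, seed=int(s))
            slp_profiles.append([sweep[l] for l in sorted(sweep)])
            tp.append(cross_validate(G, y, method="nprop",
                                     protocol=CVProtocol(seed=int(s))).auroc)
        per_lam_mean = np.mean(slp_profiles, axis=0)
        out[pattern] = {
            "slp_best_lambda_auroc": float(per_lam_mean.max()),
            "threeprop_auroc": float(np.mean(tp)),
        }
    return out


def weight_sign_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Fraction of seeds with the expected sign of the first-step weight."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    out = {}
    for pattern, want in (("assortative", 1), ("disassortative", -1)):
        hits = 0
        for s in seeds:
            G, y = generate(default_spec(pattern, seed=int(s)))
            w, _ = fit_weights(normalize_symmetric(G), y, split_seed=int(s))
            hits += int(np.sign(w.w[0]) == want)
        out[pattern] = hits / n_seeds
    return out


def mixing_diagnostics(seed: int) -> dict:
    """Median TV at r=3 and r=10 plus the stationary residual, per regime."""
    out = {}
    for pattern in ("assortative", "shared_neighbor"):
        G, _ = generate(default_spec(pattern, seed=seed))
        rep = mixing_report(G, n_starts=100, r_max=10, seed=seed)
        pi = stationary_distribution(G)
        P = normalize_asymmetric(G).M
        out[pattern] = {
            "tv_r3": float(rep["median"][3]),
            "tv_r10": float(rep["median"][10]),
            "stationary_residual": float(np.abs(pi @ P - pi).max()),
            "n_nodes": G.n_nodes,
        }
    return out
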