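"""Random-effects Bayesian model selection across subjects.

Per-subject BIC values are converted to approximate log model evidences
(log evidence ~ -BIC/2, the standard Laplace-style bridge; any additive
constant cancels in the renormalizations below).  A variational
random-effects scheme (Stephan et al.'s hierarchical model over model
frequencies) then estimates a Dirichlet posterior over family frequencies
in the cohort, from which each family's *exceedance probability* -- the
posterior probability that it is the most frequent generator -- is
computed by Monte Carlo (closed form via the Beta distribution for two
families).

Group-averaged parameters weight each subject's fitted parameters by the
renormalized evidences of that subject's *plausible* families (evidence
ratio to the subject's best family of at least 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .distmodels import FAMILIES
from .fitting import SubjectFitSet

__all__ = [
    "GroupBMSResult",
    "evidence_from_bic",
    "evidence_matrix",
    "bms_dirichlet",
    "group_average_params",
    "compare_groups_logbf",
    "logbf_verbal_scale",
]


def evidence_from_bic(fitset: SubjectFitSet) -> dict:
    """Per-family approximate log evidence (-BIC/2) for one subject.

    Non-converged families are omitted; downstream renormalization is
    row-wise over the available families.  Requires at least two converged
    fits to be informative.
    """
    usable = fitset.converged_fits()
    if len(usable) < 2:
        raise ValueError(
            f"subject {fitset.subject_id}: fewer than 2 converged fits"
        )
    return {fam: -res.bic / 2.0 for fam, res in usable.items()}


def evidence_matrix(fitsets, families=FAMILIES) -> pd.DataFrame:
    """Subjects x families DataFrame of log evidences (NaN where missing).

    Subjects with fewer than two converged fits are dropped.
    """
    rows = {}
    for fs in fitsets:
        try:
            rows[fs.subject_id] = evidence_from_bic(fs)
        except ValueError:
            continue
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=list(families))


@dataclass
class GroupBMSResult:
    families: tuple
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance: np.ndarray
    n_subjects: int
    mc_samples: int
    seed: int
    converged: bool = True
    n_iter: int = 0

    def winner(self) -> str:
        return self.families[int(np.argmax(self.exceedance))]

    def as_series(self, what: str = "exceedance") -> pd.Series:
        return pd.Series(getattr(self, what), index=list(self.families))

    def to_dict(self) -> dict:
        return {
            "families": list(self.families),
            "dirichlet_alpha": [float(v) for v in self.dirichlet_alpha],
            "expected_frequencies": [float(v) for v in self.expected_frequencies],
            "exceedance": [float(v) for v in self.exceedance],
            "n_subjects": self.n_subjects,
            "mc_samples": self.mc_samples,
            "seed": self.seed,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def dirichlet_exceedance(alpha, mc_samples: int = 1_000_000, seed: int = 0) -> np.ndarray:
    """P(frequency_k is the largest) under Dirichlet(alpha).

    Exact via the Beta distribution for two components; Monte Carlo with a
    recorded seed otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.size
    if k == 2:
        p1 = float(stats.beta.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    phi = np.zeros(k)
    remaining = mc_samples
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        phi += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return phi / mc_samples


def bms_dirichlet(
    evidence: pd.DataFrame,
    prior_alpha: float = 1.0,
    mc_samples: int = 1_000_000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> GroupBMSResult:
    """Variational random-effects model selection over families.

    ``evidence`` holds per-subject log evidences (NaN = family unavailable
    for that subject; its responsibility is renormalized over the rest).
    """
    ev = evidence.to_numpy(dtype=float)
    n, k = ev.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 families")
    mask = np.isfinite(ev)
    if not mask.any(axis=1).all():
        raise ValueError("a subject has no finite evidence")
    logev = np.where(mask, ev, -np.inf)

    alpha = np.full(k, float(prior_alpha))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = logev + special.digamma(alpha) - special.digamma(alpha.sum())
        w -= w.max(axis=1, keepdims=True)
        u = np.exp(w)
        u /= u.sum(axis=1, keepdims=True)
        new_alpha = prior_alpha + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            converged = True
            break
        alpha = new_alpha
    phi = dirichlet_exceedance(alpha, mc_samples=mc_samples, seed=seed)
    return GroupBMSResult(
        families=tuple(evidence.columns),
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=phi,
        n_subjects=n,
        mc_samples=mc_samples,
        seed=seed,
        converged=converged,
        n_iter=it,
    )


def group_average_params(
    fitsets,
    family: str,
    evidence: pd.DataFrame | None = None,
    plausibility_ratio: float = 0.05,
):
    """Evidence-weighted group averages of one family's fitted parameters.

    A family is *plausible* for a subject when its model evidence is at
    least ``plausibility_ratio`` times the subject's best evidence; within
    each subject, evidences renormalized over the plausible set give the
    weights.  Subjects for which the family is implausible contribute
    nothing.  Returns ``None`` (an "NA" marker) if the family is plausible
    for no subject.
    """
    if evidence is None:
        evidence = evidence_matrix(fitsets)
    log_ratio_floor = math.log(plausibility_ratio)
    by_id = {fs.subject_id: fs for fs in fitsets}
    num, den = {}, 0.0
    weights_used = {}
    for sid in evidence.index:
        row = evidence.loc[sid]
        finite = row.dropna()
        if family not in finite.index:
            continue
        best = finite.max()
        plausible = finite[finite - best >= log_ratio_floor]
        if family not in plausible.index:
            continue
        w = np.exp(plausible - plausible.max())
        w /= w.sum()
        weight = float(w[family])
        fit = by_id[sid].fits[family]
        for pname, pval in fit.spec.params.items():
            num[pname] = num.get(pname, 0.0) + weight * pval
        den += weight
        weights_used[sid] = weight
    if den == 0.0:
        return None
    return {
        "params": {p: v / den for p, v in num.items()},
        "weights": weights_used,
        "n_subjects": len(weights_used),
    }


def compare_groups_logbf(durations_a, durations_b, family: str,
                         x_min: float = 1.0, n_starts: int = 5,
                         seed: int = 0) -> float:
    """Log Bayes factor: separate per-group fits vs one pooled fit.

    Evidence of each hypothesis is approximated by -BIC/2 of the
    family's MLE fit.  Positive values favor distinct distributions;
    |LogBF| > 5 is conventionally read as strong evidence.
    """
    from .fitting import fit_mle

    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    fit_a = fit_mle(family, a, x_min, n_starts=n_starts, seed=seed,
                    compute_ks=False)
    fit_b = fit_mle(family, b, x_min, n_starts=n_starts, seed=seed + 1,
                    compute_ks=False)
    fit_ab = fit_mle(family, np.concatenate([a, b]), x_min,
                     n_starts=n_starts, seed=seed + 2, compute_ks=False)
    for f in (fit_a, fit_b, fit_ab):
        if not (f.converged and math.isfinite(f.bic)):
            raise RuntimeError("compare_groups_logbf: a component fit failed")
    return (-fit_a.bic / 2.0 - fit_b.bic / 2.0) - (-fit_ab.bic / 2.0)


def logbf_verbal_scale(logbf: float) -> str:
    """Conventional verbal strength of |LogBF| evidence."""
    m = abs(logbf)
    if m > 5:
        return "strong"
    if m > 3:
        return "moderate"
    if m > 1:
        return "weak"
    return "inconclusive"
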