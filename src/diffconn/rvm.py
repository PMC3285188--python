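"""Random-variance-model moderated paired t-test with FDR control.

For gene ``g`` with per-patient paired differences (post - pre) the
ordinary paired t-test uses the gene's own sample variance ``s2`` on
``m = n - 1`` degrees of freedom — hopeless at n of 3-6 patients.  The
random variance model shares variance information across genes by assuming
the gene-wise precision is Gamma distributed,

    1 / sigma_g^2  ~  Gamma(shape a, scale b),

i.e. an inverse-gamma prior on the variances.  Under that prior the sample
variances satisfy ``s2 * a * b ~ F(m, 2a)``, so (a, b) can be estimated
once by maximum marginal likelihood over all genes, and each gene's
variance is replaced by its posterior mean

    s2_tilde = (m * s2 + 2/b) / (m + 2a),

yielding a moderated t statistic with ``m + 2a`` degrees of freedom.
Benjamini-Hochberg FDR is applied across genes; a gene's direction is
``Up`` iff its mean difference is positive (higher expression after
treatment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy

log = logging.getLogger(__name__)

__all__ = [
    "RVMPrior",
    "RVMFitError",
    "paired_differences",
    "rvm_fit",
    "rvm_paired_test",
    "select_de_genes",
    "classify_cross_group",
]


class RVMFitError(RuntimeError):
    """Marginal-likelihood fit failed; carries the last iterate."""

    def __init__(self, message: str, last_iterate: tuple[float, float] | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class RVMPrior:
    """Fitted gamma prior on gene-wise precision (shape ``a``, scale ``b``)."""

    a: float
    b: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("prior parameters must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("prior parameters must be positive")


def paired_differences(study: ExpressionStudy, group: str) -> pd.DataFrame:
    """Per-gene (post - pre) differences, one column per patient."""
    patients = study.patients(group=group)
    if len(patients) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 patient pairs")
    design = study.design
    cols = {}
    for pid in patients:
        rows = design[design["patient_id"] == pid]
        pre = rows.index[rows["timepoint"] == "pre"][0]
        post = rows.index[rows["timepoint"] == "post"][0]
        cols[pid] = study.matrix[post] - study.matrix[pre]
    return pd.DataFrame(cols, index=study.matrix.index)


def _nll(theta: np.ndarray, s2: np.ndarray, m: float) -> float:
    a, b = np.exp(theta)
    ab = a * b
    # density of s2 when s2*a*b ~ F(m, 2a)
    return -float(np.sum(np.log(ab) + stats.f.logpdf(ab * s2, m, 2.0 * a)))


def rvm_fit(variances: np.ndarray | pd.Series, m: int) -> RVMPrior:
    """Fit the precision prior (a, b) to gene-wise sample variances.

    Maximizes the marginal likelihood of the variances under
    ``s2 * a * b ~ F(m, 2a)``.  Requires at least 50 finite positive
    variances (with fewer genes, use the ordinary paired t-test instead).
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    s2 = s2[s2 > 0]
    if s2.size < 50:
        raise ValueError(
            f"only {s2.size} usable variances; the prior fit needs >= 50 "
            "(fall back to the ordinary paired t-test)"
        )
    if m < 1:
        raise ValueError("degrees of freedom m must be >= 1")
    mean = float(np.mean(s2))
    starts = [(2.0, 1.0 / mean), (1.5, 0.5 / mean), (4.0, 2.0 / mean)]
    best = None
    for a0, b0 in starts:
        res = optimize.minimize(
            _nll,
            x0=np.log([a0, b0]),
            args=(s2, float(m)),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    if not best.success or not np.isfinite(best.fun):
        raise RVMFitError(
            f"marginal-likelihood fit did not converge: {best.message}",
            last_iterate=(float(a), float(b)),
        )
    if a > 1e4:
        # essentially equal variances: the prior degenerates to a point mass
        raise RVMFitError(
            "degenerate fit (a -> infinity): variances are effectively equal; "
            "moderation is a no-op, use the ordinary paired t-test",
            last_iterate=(float(a), float(b)),
        )
    return RVMPrior(a=float(a), b=float(b), converged=bool(best.success))


def rvm_paired_test(
    differences: pd.DataFrame,
    prior: RVMPrior | None = None,
    plain: bool = False,
) -> pd.DataFrame:
    """Moderated (or, with ``plain=True``, ordinary) paired t-test per gene.

    Returns a DataFrame indexed by gene with columns ``dbar`` (mean log2
    difference), ``s2``, ``s2_tilde``, ``t``, ``df``, ``p``, ``q`` and
    ``direction``.
    """
    X = differences.to_numpy(dtype=float)
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 patient pairs")
    m = n - 1
    dbar = X.mean(axis=1)
    s2 = X.var(axis=1, ddof=1)
    if plain:
        s2_tilde = s2
        df = float(m)
    else:
        if prior is None:
            prior = rvm_fit(s2, m)
        s2_tilde = (m * s2 + 2.0 / prior.b) / (m + 2.0 * prior.a)
        df = float(m + 2.0 * prior.a)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = dbar / np.sqrt(s2_tilde / n)
    t = np.where(dbar == 0, 0.0, t)  # 0/0 when a plain-mode variance is zero
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "dbar": dbar,
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t": t,
            "df": df,
            "p": p,
            "q": q,
            "direction": np.where(dbar > 0, "Up", "Down"),
        },
        index=differences.index,
    )


def select_de_genes(
    results: pd.DataFrame, p_thr: float = 0.05, q_thr: float = 0.05
) -> pd.DataFrame:
    """Genes passing ``p < p_thr`` and ``q < q_thr``; counts are logged."""
    for thr, name in ((p_thr, "p_thr"), (q_thr, "q_thr")):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1]")
    hit = results[(results["p"] < p_thr) & (results["q"] < q_thr)]
    n_up = int((hit["direction"] == "Up").sum())
    log.info(
        "selected %d genes (p<%g, FDR<%g): %d Up, %d Down",
        len(hit), p_thr, q_thr, n_up, len(hit) - n_up,
    )
    return hit


def classify_cross_group(
    de_if: pd.DataFrame, de_id: pd.DataFrame
) -> pd.Series:
    """Cross-group direction classes for the union of selected genes.

    A gene selected in both groups is ``Up``/``Down`` when the directions
    agree and ``Other`` when they disagree; a gene selected in one group
    keeps its single-group direction.
    """
    out: dict[str, str] = {}
    dir_if = de_if["direction"].to_dict()
    dir_id = de_id["direction"].to_dict()
    for g in sorted(set(dir_if) | set(dir_id)):
        a, b = dir_if.get(g), dir_id.get(g)
        if a is not None and b is not None and a != b:
            out[g] = "Other"
        else:
            out[g] = a if a is not None else b
    return pd.Series(out, dtype=object)


def write_de_table(results: pd.DataFrame, path, params: dict | None = None) -> None:
    """TSV export with a header comment recording the parameters used."""
    with open(path, "w") as fh:
        if params:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        results.to_csv(fh, sep="\t", index_label="gene")
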