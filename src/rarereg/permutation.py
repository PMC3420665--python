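"""Permutation inference with model selection embedded in every permutation.

Because each regression method tunes its own complexity (number of
components, penalty, sparsity) on the data, asymptotic reference
distributions for the fit statistics are biased.  Significance is
therefore assessed by permuting the phenotype against the (fixed)
genotype rows and redoing *all* model-fitting steps — including AIC/BIC/
GIC minimization and component-count selection — inside each permutation.
Pooled predictor columns are not rebuilt under permutation since the
genotypes do not change.

The empirical p-value uses the add-one convention
p = (1 + #{perm stats >= observed}) / (B + 1), so p is always valid and
its floor is 1/(B+1).  Randomness comes from ``numpy.random.Generator``
(PCG64); identical seeds give bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import models
from .comparators import skat_weights, vt_thresholds, we_weights
from .genotype import AugmentedDesign, GenotypeMatrix, build_pooled_variables
from .models import ModelFit, SelectionCriterion

__all__ = ["PermutationResult", "MethodSpec", "permutation_pvalue", "run_test"]

REGRESSION_METHODS = ("PCR", "PLS", "SPLS", "LASSO", "RR")
COMPARATOR_METHODS = ("WE", "VT", "SKAT")
RNG_ALGORITHM = "PCG64"


@dataclass
class PermutationResult:
    """Observed statistic, permutation draws and the empirical p-value."""

    method_label: str
    observed: float
    perm_stats: np.ndarray
    p_value: float
    B: int
    seed: int | None = None
    rng_algorithm: str = RNG_ALGORITHM
    observed_fit: ModelFit | None = None
    selected_labels: list[str] = field(default_factory=list)

    def to_record(self) -> dict:
        return {
            "method": self.method_label,
            "observed": self.observed,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "rng_algorithm": self.rng_algorithm,
            "selected_variants": self.selected_labels,
        }


def permutation_pvalue(
    statistic,
    y: np.ndarray,
    B: int,
    rng: np.random.Generator,
    observed: float | None = None,
    early_stop_r: int | None = None,
) -> tuple[float, np.ndarray, float, int]:
    """Empirical p-value of ``statistic`` under phenotype permutation.

    ``statistic`` maps a phenotype vector to a scalar oriented so larger
    means more extreme; it is re-evaluated in full on every permuted
    phenotype.  A permutation whose evaluation raises is scored -inf
    (never extreme) with a warning.  With ``early_stop_r`` set, sampling
    stops once that many exceedances accumulate and p = r / B_used.

    Returns ``(observed, perm_stats, p_value, B_used)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(y, dtype=float)
    if observed is None:
        observed = float(statistic(y))
    stats_out = np.empty(B)
    r = 0
    used = 0
    for b in range(B):
        y_perm = rng.permutation(y)
        try:
            s = float(statistic(y_perm))
        except Exception as exc:  # statistic failures count as non-extreme
            warnings.warn(f"permutation {b} failed ({exc!r}); scored -inf")
            s = -np.inf
        stats_out[b] = s
        used = b + 1
        if s >= observed:
            r += 1
            if early_stop_r is not None and r >= early_stop_r:
                break
    stats_out = stats_out[:used]
    if early_stop_r is not None and r >= early_stop_r:
        p = r / used
    else:
        p = (1 + r) / (used + 1)
    return observed, stats_out, p, used


@dataclass(frozen=True)
class MethodSpec:
    """One test configuration, in the nomenclature of the output labels.

    ``method`` is one of PCR, PLS, SPLS, LASSO, RR, WE, VT, SKAT.  For
    PCR/PLS, ``selector`` is 'one' (label Comp1) or 'variance_explained'
    (label Compk, with cutoff ``theta``); RR takes a ridge penalty
    ``lam``; LASSO/SPLS take an information criterion.  ``pooled`` adds
    the variable-threshold pooled columns to the predictor space and a
    '.p' suffix to the label.
    """

    method: str
    selector: str = "variance_explained"
    theta: float = 0.80
    lam: float = 10.0
    criterion: str = "aic"
    pooled: bool = False
    K_max: int | None = None
    eta_grid: tuple[float, ...] | None = None

    @classmethod
    def parse(cls, text: str) -> "MethodSpec":
        """Parse compact specs like 'RR.l0', 'PCR.Comp1.p', 'LASSO.BIC'."""
        tokens = text.strip().split(".")
        pooled = False
        if tokens and tokens[-1] == "p":
            pooled = True
            tokens = tokens[:-1]
        if not tokens:
            raise ValueError(f"empty method spec {text!r}")
        name = tokens[0].upper()
        if name not in REGRESSION_METHODS + COMPARATOR_METHODS:
            raise ValueError(f"unknown method {tokens[0]!r}")
        spec = cls(method=name, pooled=pooled)
        for tok in tokens[1:]:
            low = tok.lower()
            if low == "comp1":
                spec = replace(spec, selector="one")
            elif low == "compk":
                spec = replace(spec, selector="variance_explained")
            elif low in ("aic", "bic", "gic"):
                spec = replace(spec, criterion=low)
            elif low.startswith("l") and low[1:].replace("-", "").replace("e", "").replace(".", "").isdigit():
                spec = replace(spec, lam=float(low[1:]))
            else:
                raise ValueError(f"unknown option {tok!r} in method spec {text!r}")
        return spec

    @property
    def label(self) -> str:
        if self.method == "RR":
            base = f"RR λ={self.lam:g}"
        elif self.method in ("PCR", "PLS"):
            base = f"{self.method} {'Comp1' if self.selector == 'one' else 'Compk'}"
        elif self.method in ("LASSO", "SPLS"):
            base = f"{self.method}.{self.criterion.upper()}"
        else:
            base = self.method
        return base + (".p" if self.pooled else "")


def _make_statistic(spec: MethodSpec, G: GenotypeMatrix, X: np.ndarray):
    """Bind a phenotype -> statistic callable, precomputing genotype-side work."""
    if spec.method == "WE":
        s = G.values @ we_weights(G)
        sc = s - s.mean()
        ns = np.linalg.norm(sc)

        def stat(y):
            yc = y - y.mean()
            denom = np.linalg.norm(yc) * ns
            return abs(float(yc @ sc)) / denom if denom > 0 else 0.0

        return stat

    if spec.method == "VT":
        thresholds = vt_thresholds(G)
        cols, norms = [], []
        for t in thresholds:
            members = G.maf <= t
            if not members.any():
                continue
            C = G.values[:, members].sum(axis=1)
            nrm = float(np.linalg.norm(C))
            if nrm > 0:
                cols.append(C)
                norms.append(nrm)
        if not cols:
            return lambda y: 0.0
        Cmat = np.column_stack(cols)
        norms = np.asarray(norms)

        def stat(y):
            yc = y - y.mean()
            return float(np.max(np.abs(yc @ Cmat) / norms))

        return stat

    if spec.method == "SKAT":
        GW = G.values * skat_weights(G.maf)

        def stat(y):
            r = y - y.mean()
            v = GW.T @ r
            return float(v @ v)

        return stat

    # regression methods operate on the (possibly augmented) design
    Xc = X - X.mean(axis=0)

    if spec.method == "RR":
        U, d, _, rank = models._svd(Xc)
        U, d = U[:, :rank], d[:rank]
        shrink = d**2 / (d**2 + spec.lam)

        def stat(y):
            yc = y - y.mean()
            uy = U.T @ yc
            f = U @ (shrink * uy)
            denom = np.linalg.norm(yc) * np.linalg.norm(f)
            return float(yc @ f / denom) if denom > 0 else 0.0

        return stat

    if spec.method == "PCR":
        U, d, _, rank = models._svd(Xc)
        U = U[:, :rank]

        def stat(y):
            yc = y - y.mean()
            tss = float(yc @ yc)
            if tss <= 0:
                return 0.0
            uy = U.T @ yc
            cum = np.cumsum(uy**2)
            if spec.selector == "one":
                k = 1
            else:
                if cum[-1] <= 0:
                    return 0.0
                k = int(np.argmax(cum >= spec.theta * cum[-1] - 1e-12) + 1)
            # corr(y, yhat) = sqrt(explained SS / TSS) for a projection fit
            return float(np.sqrt(max(cum[k - 1], 0.0) / tss))

        return stat

    if spec.method == "PLS":
        _, _, _, rank = models._svd(Xc)
        k_path = 1 if spec.selector == "one" else rank

        def stat(y):
            yc = y - y.mean()
            tss = float(yc @ yc)
            if tss <= 0:
                return 0.0
            _, _, _, _, cum_fit = models._pls_path(Xc, yc, k_path)
            if not cum_fit:
                return 0.0
            if spec.selector == "one":
                f = cum_fit[0]
            else:
                r2 = np.array([1.0 - float((yc - f) @ (yc - f)) / tss for f in cum_fit])
                if r2[-1] <= 0:
                    return 0.0
                k = int(np.argmax(r2 >= spec.theta * r2[-1] - 1e-12) + 1)
                f = cum_fit[k - 1]
            denom = np.linalg.norm(yc) * np.linalg.norm(f)
            return float(yc @ f / denom) if denom > 0 else 0.0

        return stat

    if spec.method == "LASSO":
        crit = SelectionCriterion(spec.criterion)

        def stat(y):
            return models.lasso_select(X, y, crit).fit_statistic

        return stat

    if spec.method == "SPLS":
        crit = SelectionCriterion(spec.criterion)
        eta = np.asarray(spec.eta_grid) if spec.eta_grid is not None else None

        def stat(y):
            return models.spls_select(X, y, spec.K_max, eta, crit).fit_statistic

        return stat

    raise ValueError(f"unknown method {spec.method!r}")


def observed_fit(spec: MethodSpec, G: GenotypeMatrix, X: np.ndarray, y: np.ndarray) -> ModelFit | None:
    """The full ModelFit on the unpermuted data (regression methods only)."""
    y = np.asarray(y, float)
    if spec.method == "RR":
        return models.fit_ridge(X, y, spec.lam)
    if spec.method == "PCR":
        k = models.choose_k(X, y, spec.selector, spec.theta, "pcr")
        return models.fit_pcr(X, y, k)
    if spec.method == "PLS":
        k = models.choose_k(X, y, spec.selector, spec.theta, "pls")
        return models.fit_pls(X, y, k)
    if spec.method == "LASSO":
        return models.lasso_select(X, y, SelectionCriterion(spec.criterion))
    if spec.method == "SPLS":
        eta = np.asarray(spec.eta_grid) if spec.eta_grid is not None else None
        return models.spls_select(X, y, spec.K_max, eta, SelectionCriterion(spec.criterion))
    return None


def run_test(
    method: str | MethodSpec,
    G: GenotypeMatrix,
    y: np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    design: AugmentedDesign | None = None,
    early_stop_r: int | None = None,
) -> PermutationResult:
    """Run one association test on a gene with permutation significance.

    ``method`` is a :class:`MethodSpec` or its compact string form (e.g.
    ``"RR.l0"``, ``"PCR.Comp1.p"``, ``"LASSO.BIC"``).  The design for
    regression methods is the genotype matrix, augmented with pooled
    columns when the spec asks for them; a prebuilt
    :class:`AugmentedDesign` can be passed to avoid recomputation.
    """
    spec = MethodSpec.parse(method) if isinstance(method, str) else method
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    if np.isnan(G.values).any():
        raise ValueError("impute missing genotypes before testing")

    if spec.method in REGRESSION_METHODS and spec.pooled:
        if design is None:
            design = build_pooled_variables(G)
        X = design.matrix
        labels = design.column_labels(G.variant_ids)
    else:
        X = G.values
        labels = list(G.variant_ids)

    if rng is None:
        rng = np.random.default_rng(seed)
    statistic = _make_statistic(spec, G, X)
    fit = observed_fit(spec, G, X, y)
    obs = fit.fit_statistic if fit is not None else float(statistic(y))
    observed, perm_stats, p, used = permutation_pvalue(
        statistic, y, B, rng, observed=obs, early_stop_r=early_stop_r
    )
    sel_labels: list[str] = []
    if fit is not None and fit.selected is not None and spec.method in ("LASSO", "SPLS"):
        sel_labels = [labels[j] for j in fit.selected]
    return PermutationResult(
        method_label=spec.label,
        observed=observed,
        perm_stats=perm_stats,
        p_value=p,
        B=used,
        seed=seed,
        observed_fit=fit,
        selected_labels=sel_labels,
    )
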