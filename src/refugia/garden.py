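"""Variance components of common-garden provenance trials.

The phenotypic observation of tree *l* in the plot of provenance *i*,
site *j*, block *k* is modelled as

    Y_ijkl = μ + P_i + S_j + (P×S)_ij + B(S)_(j)k + (P×B(S))_(i(j)k) + e_l(ijk)

with every term after μ an independent mean-zero Gaussian random effect.
The residual e carries the environmental error plus within-family
variation inside a plot; fitted separately per region of origin (all
provenances sharing the garden environment), differences in the residual
component estimate differences in within-population genetic variance.
For traits measured at a single site the site and provenance × site
terms drop and block-within-site becomes a simple block effect.

Estimation is restricted maximum likelihood (REML) with the variance
ratios profiled against the residual, optimised under non-negativity
constraints; standard errors come from the observed information matrix
at the optimum (undefined for components estimated on the zero
boundary), analogous to the COVTEST output of mixed-model software.

The module is organised statsmodels-style:
:class:`VarianceComponentsModel` is built from a long-format phenotype
table and ``fit()`` returns a :class:`VarianceComponentsResults`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "VarianceComponentsModel", "VarianceComponentsResults",
    "fit_variance_model", "region_trait_table", "provenance_summaries",
    "pca", "OrdinationResult",
]

_MULTI_SITE_TERMS = (
    "provenance", "site", "provenance_x_site",
    "block_in_site", "provenance_x_block",
)
_SINGLE_SITE_TERMS = ("provenance", "block", "provenance_x_block")


def _same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two factor code arrays induce the same grouping."""
    na, nb = a.max() + 1, b.max() + 1
    if na != nb:
        return False
    return len(set(zip(a.tolist(), b.tolist()))) == na


def _one_hot(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = codes.size
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class VarianceComponentsModel:
    """REML model of the random-effects trial decomposition.

    Parameters
    ----------
    data
        Long-format table with columns ``provenance``, ``site``,
        ``block``, ``tree`` and the response column.
    response
        Name of the response column (default ``"value"``).
    multi_site
        Include site and provenance × site terms.  Default: inferred
        from the number of distinct sites in the data.
    """

    def __init__(self, data: pd.DataFrame, response: str = "value",
                 multi_site: bool | None = None):
        required = {"provenance", "site", "block", response}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks column(s): {sorted(missing)}")
        data = data.loc[np.isfinite(data[response].to_numpy(dtype=float))]
        if data.empty:
            raise ValueError("no finite observations")
        self.data = data.reset_index(drop=True)
        self.response = response
        y = self.data[response].to_numpy(dtype=float)

        prov = self.data["provenance"].astype(str)
        site = self.data["site"].astype(str)
        block = self.data["block"].astype(str)
        if multi_site is None:
            multi_site = site.nunique() > 1
        self.multi_site = bool(multi_site)

        if self.multi_site:
            factors = {
                "provenance": prov,
                "site": site,
                "provenance_x_site": prov + "|" + site,
                "block_in_site": site + "|" + block,
                "provenance_x_block": prov + "|" + site + "|" + block,
            }
        else:
            factors = {
                "provenance": prov,
                "block": block,
                "provenance_x_block": prov + "|" + block,
            }
        # retain a term only if it has >= 2 levels and does not duplicate
        # the partition of an already retained term (e.g. provenance×block
        # collapses onto provenance when there is a single block)
        blocks_Z = []
        retained: list[str] = []
        dropped: list[str] = []
        kept_codes: list[np.ndarray] = []
        self._slices: dict[str, slice] = {}
        start = 0
        for name, fac in factors.items():
            codes, levels = pd.factorize(fac, sort=True)
            if len(levels) < 2 or any(
                _same_partition(kc, codes) for kc in kept_codes
            ):
                dropped.append(name)
                continue
            kept_codes.append(codes)
            retained.append(name)
            blocks_Z.append(_one_hot(codes, len(levels)))
            self._slices[name] = slice(start, start + len(levels))
            start += len(levels)
        if not retained:
            raise ValueError("no identifiable random terms besides the residual")
        self.terms = tuple(retained)
        self.dropped_terms = tuple(dropped)
        # within-plot replication is what identifies the residual
        plot = prov + "|" + site + "|" + block
        if plot.value_counts().max() < 2:
            raise ValueError(
                "degenerate design: no replication within plots, the "
                "residual variance is not identifiable"
            )
        Z = sp.hstack(blocks_Z, format="csr")
        self.n = y.size
        self.q = Z.shape[1]
        self.y = y
        # centring the response is a fixed-effect shift (REML-invariant)
        # and avoids cancellation in y'Py when the mean is large
        self._ybar = float(y.mean())
        yc = y - self._ybar
        self._ZtZ = (Z.T @ Z).toarray()
        self._Zty = Z.T @ yc
        self._Zt1 = np.asarray(Z.sum(axis=0)).ravel()
        self._yty = float(yc @ yc)
        self._ysum = float(yc.sum())

    # ------------------------------------------------------------------
    def _core(self, gamma: np.ndarray):
        """Woodbury pieces shared by the criterion and the likelihood.

        With H = I + Z diag(γ) Z', returns
        (log|H|, 1'H⁻¹1, 1'H⁻¹y, y'P y) where P projects out the mean.
        """
        d = np.empty(self.q)
        for g, name in zip(gamma, self.terms):
            d[self._slices[name]] = g
        sd = np.sqrt(d)
        A = (sd[:, None] * self._ZtZ) * sd[None, :]
        A[np.diag_indices_from(A)] += 1.0
        c, low = cho_factor(A, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        u1 = sd * self._Zt1
        uy = sd * self._Zty
        sol = cho_solve((c, low), np.column_stack([u1, uy]),
                        check_finite=False)
        a1, ay = sol[:, 0], sol[:, 1]
        one_h_one = self.n - u1 @ a1
        one_h_y = self._ysum - u1 @ ay
        y_h_y = self._yty - uy @ ay
        ypy = y_h_y - one_h_y**2 / one_h_one
        return logdet, one_h_one, one_h_y, max(ypy, 1e-300)

    def _criterion(self, gamma: np.ndarray) -> float:
        """Negative profiled REML criterion (σ²_e concentrated out)."""
        logdet, one_h_one, _, ypy = self._core(gamma)
        return ((self.n - 1) * np.log(ypy / (self.n - 1))
                + logdet + np.log(one_h_one))

    def reml_loglik(self, variances: np.ndarray) -> float:
        """REML log-likelihood (up to constant) at a full variance vector
        (components in term order, residual last)."""
        sig = np.asarray(variances, dtype=float)
        s2e = sig[-1]
        if s2e <= 0:
            return -np.inf
        gamma = np.maximum(sig[:-1], 0.0) / s2e
        logdet, one_h_one, _, ypy = self._core(gamma)
        return -0.5 * ((self.n - 1) * np.log(s2e) + logdet
                       + np.log(one_h_one) + ypy / s2e)

    # ------------------------------------------------------------------
    def fit(self, start: np.ndarray | None = None,
            maxiter: int = 500) -> "VarianceComponentsResults":
        """Maximise the REML likelihood and assemble results."""
        k = len(self.terms)
        y = self.y
        names = list(self.terms) + ["residual"]

        if np.var(y) < 1e-12 * max(1.0, abs(y.mean())) ** 2 or np.var(y) == 0:
            # constant response: everything is the mean
            params = pd.Series(np.zeros(k + 1), index=names)
            bse = pd.Series(np.full(k + 1, np.nan), index=names)
            return VarianceComponentsResults(
                self, params, bse, mu=float(y.mean()), converged=True,
                loglik=np.nan,
            )

        x0 = np.full(k, 0.1) if start is None else np.asarray(start, float)
        bounds = [(0.0, 1e6)] * k
        res = minimize(self._criterion, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "ftol": 1e-12,
                                "gtol": 1e-8})
        best = res
        # a second start guards against flat-likelihood stalls
        res2 = minimize(self._criterion, np.full(k, 1.0), method="L-BFGS-B",
                        bounds=bounds,
                        options={"maxiter": maxiter, "ftol": 1e-12,
                                 "gtol": 1e-8})
        if res2.fun < best.fun - 1e-10:
            best = res2
        gamma = np.maximum(best.x, 0.0)
        # snap tiny ratios to the boundary
        gamma[gamma < 1e-10] = 0.0

        logdet, one_h_one, one_h_y, ypy = self._core(gamma)
        s2e = ypy / (self.n - 1)
        sig = np.append(gamma * s2e, s2e)
        mu = self._ybar + one_h_y / one_h_one
        loglik = self.reml_loglik(sig)
        bse = self._standard_errors(sig)
        params = pd.Series(sig, index=names)
        return VarianceComponentsResults(
            self, params, pd.Series(bse, index=names), mu=float(mu),
            converged=bool(best.success), loglik=float(loglik),
        )

    def _standard_errors(self, sig: np.ndarray) -> np.ndarray:
        """Asymptotic SEs from the observed information (finite-difference
        Hessian of the REML log-likelihood); NaN on the zero boundary."""
        free = np.flatnonzero(sig > 1e-10)
        se = np.full(sig.size, np.nan)
        if free.size == 0:
            return se
        steps = np.maximum(1e-4 * sig[free], 1e-7)

        def ll(theta_free: np.ndarray) -> float:
            full = sig.copy()
            full[free] = theta_free
            return self.reml_loglik(full)

        m = free.size
        H = np.empty((m, m))
        f0 = ll(sig[free])
        for i in range(m):
            for j in range(i, m):
                hi, hj = steps[i], steps[j]
                ti = sig[free].copy()
                if i == j:
                    tp = ti.copy(); tp[i] += hi
                    tm = ti.copy(); tm[i] = max(tm[i] - hi, 1e-12)
                    hm = ti[i] - tm[i]
                    H[i, i] = (ll(tp) - f0) / hi - (f0 - ll(tm)) / hm
                    H[i, i] /= 0.5 * (hi + hm)
                else:
                    tpp = ti.copy(); tpp[i] += hi; tpp[j] += hj
                    tpm = ti.copy(); tpm[i] += hi; tpm[j] = max(tpm[j] - hj, 1e-12)
                    tmp = ti.copy(); tmp[i] = max(tmp[i] - hi, 1e-12); tmp[j] += hj
                    tmm = ti.copy()
                    tmm[i] = max(tmm[i] - hi, 1e-12)
                    tmm[j] = max(tmm[j] - hj, 1e-12)
                    dif_i = ti[i] - tmm[i]
                    dif_j = ti[j] - tmm[j]
                    H[i, j] = H[j, i] = (
                        ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)
                    ) / ((hi + dif_i) * (hj + dif_j))
        try:
            cov = np.linalg.inv(-H)
            diag = np.diag(cov)
            with np.errstate(invalid="ignore"):
                se[free] = np.where(diag > 0, np.sqrt(diag), np.nan)
        except np.linalg.LinAlgError:
            pass
        return se


class VarianceComponentsResults:
    """Fitted variance components with SEs, grand mean and diagnostics."""

    def __init__(self, model, params: pd.Series, bse: pd.Series,
                 mu: float, converged: bool, loglik: float):
        self.model = model
        self.params = params
        self.bse = bse
        self.mu = mu
        self.converged = converged
        self.loglik = loglik

    @property
    def residual_variance(self) -> float:
        return float(self.params["residual"])

    @property
    def residual_se(self) -> float:
        return float(self.bse["residual"])

    def summary(self) -> str:
        lines = [
            "Variance components (REML)",
            "=" * 46,
            f"observations: {self.model.n}    grand mean: {self.mu:.4f}",
            f"converged: {self.converged}    REML loglik: {self.loglik:.3f}",
            "-" * 46,
            f"{'component':<24}{'estimate':>10}{'SE':>10}",
        ]
        for name in self.params.index:
            se = self.bse[name]
            se_str = f"{se:10.4f}" if np.isfinite(se) else "       ---"
            lines.append(f"{name:<24}{self.params[name]:10.4f}{se_str}")
        return "\n".join(lines)


def fit_variance_model(table: pd.DataFrame, trait: str,
                       multi_site: bool | None = None
                       ) -> VarianceComponentsResults:
    """Fit the trial model to one trait of a long-format phenotype table.

    The table has columns (region, provenance, site, block, tree, trait,
    value); rows of other traits are ignored.
    """
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    return VarianceComponentsModel(
        sub, response="value", multi_site=multi_site
    ).fit()


def region_trait_table(table: pd.DataFrame, regions=None, traits=None):
    """Within-population variance components by region and trait.

    Fits the model separately for every region × trait combination (one
    fit each) and tabulates the residual component and its SE, mirroring
    a regional summary table.  Returns ``(summary, fits)``; combinations
    without data appear as NaN rows and are listed in
    ``summary.attrs["missing"]``.
    """
    if regions is None:
        regions = list(pd.unique(table["region"]))
    if traits is None:
        traits = list(pd.unique(table["trait"]))
    rows = []
    fits: dict[tuple[str, str], VarianceComponentsResults] = {}
    missing: list[tuple[str, str]] = []
    for region in regions:
        row: dict[str, float | str] = {"region": region}
        for trait in traits:
            sub = table[(table["region"] == region)
                        & (table["trait"] == trait)]
            if sub.empty:
                row[trait] = np.nan
                row[f"{trait}_se"] = np.nan
                missing.append((region, trait))
                continue
            res = fit_variance_model(sub, trait)
            fits[(region, trait)] = res
            row[trait] = res.residual_variance
            row[f"{trait}_se"] = res.residual_se
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary.attrs["missing"] = missing
    summary.attrs["n_fits"] = len(fits)
    return summary, fits


def provenance_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Provenance-mean matrix for ordination.

    Multi-site traits yield one column per site (``height@3``);
    single-site traits one column.  Under the balanced design the simple
    provenance mean is the least-squares mean.
    """
    cols: dict[str, pd.Series] = {}
    for trait in pd.unique(table["trait"]):
        sub = table[table["trait"] == trait]
        sites = pd.unique(sub["site"])
        if len(sites) > 1:
            for site in sorted(sites):
                s = sub[sub["site"] == site]
                cols[f"{trait}@{site}"] = s.groupby("provenance")["value"].mean()
        else:
            cols[trait] = sub.groupby("provenance")["value"].mean()
    out = pd.DataFrame(cols)
    if out.isna().any().any():
        empty = out.columns[out.isna().any()].tolist()
        raise ValueError(
            f"provenance(s) without records for variable(s) {empty}"
        )
    return out


class OrdinationResult:
    """PCA output: orthonormal loadings, scores and explained variance."""

    def __init__(self, loadings: pd.DataFrame, scores: pd.DataFrame,
                 explained_variance: np.ndarray,
                 explained_fraction: np.ndarray):
        self.loadings = loadings
        self.scores = scores
        self.explained_variance = explained_variance
        self.explained_fraction = explained_fraction


def pca(matrix: pd.DataFrame, standardize: bool = True) -> OrdinationResult:
    """Principal components of an observations × variables matrix.

    With ``standardize=True`` (default) the components are those of the
    correlation matrix.  Loadings columns are orthonormal eigenvectors;
    the sign convention makes the largest-magnitude loading of each
    component positive.  Computed by SVD of the (standardized) centred
    data.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input must be finite and complete")
    Xc = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = matrix.columns[zero].tolist()
            raise ValueError(f"zero-variance column(s): {names}")
        Xc = Xc / sd
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(n - 1, p)
    s, Vt = s[:ncomp], Vt[:ncomp]
    eig = s**2 / (n - 1)
    # deterministic signs: largest |loading| per component positive
    for i in range(ncomp):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    loadings = pd.DataFrame(
        Vt.T, index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(ncomp)],
    )
    scores = pd.DataFrame(
        Xc @ Vt.T, index=matrix.index, columns=loadings.columns
    )
    total = p if standardize else np.var(Xc, axis=0, ddof=1).sum()
    return OrdinationResult(loadings, scores, eig, eig / total)
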