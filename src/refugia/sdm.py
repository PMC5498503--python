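"""Ensemble-classifier species distribution model.

The habitat model is a bagged ensemble of classification trees relating
presence/absence records to bioclimatic covariates.  Each tree is grown
on a bootstrap sample of the training records; a cell's (or record's)
probability of presence is the *vote fraction* — the share of trees that
classify it as present.  Records left out of a tree's bootstrap sample
are that tree's out-of-bag (OOB) set, giving an internal validation
sample: the OOB vote fraction of every training record is stored on the
fitted results and scored by AUC.

Organised statsmodels-style: :class:`HabitatModel` holds the design
(covariates + labels), ``fit()`` returns a :class:`HabitatModelResults`
carrying the ensemble, OOB votes and prediction methods.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .bioclim import DEFAULT_SDM_VARIABLES, BioclimGrid
from .raster import RasterGrid
from .validation import auc

__all__ = ["extract_covariates", "HabitatModel", "HabitatModelResults"]


def extract_covariates(occurrences: pd.DataFrame, bioclim: BioclimGrid,
                       variables=DEFAULT_SDM_VARIABLES):
    """Build the model design table from occurrence records and a grid.

    Returns ``(design, n_dropped)``: one row per retained record with the
    covariate values of its containing cell plus the label (and the true
    probability column when present, for synthetic-data testing).
    Records outside the grid or on nodata cells are dropped and counted.
    """
    variables = tuple(variables)
    missing = [v for v in variables if v not in bioclim]
    if missing:
        raise KeyError(f"bioclim grid lacks variable(s): {missing}")
    template = bioclim.template
    rows, cols, inside = template.index_of(
        occurrences["lon"].to_numpy(), occurrences["lat"].to_numpy()
    )
    stack = bioclim.stack(variables)  # (n_vars, nrow, ncol)
    values = stack[:, rows, cols].T
    keep = inside & ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    design = pd.DataFrame(values[keep], columns=list(variables))
    design["label"] = occurrences["label"].to_numpy()[keep]
    if "true_prob" in occurrences.columns:
        design["true_prob"] = occurrences["true_prob"].to_numpy()[keep]
    if design.empty:
        raise ValueError("no occurrence records remain after drops")
    return design.reset_index(drop=True), n_dropped


class HabitatModel:
    """Bagged classification-tree model of presence/absence vs climate.

    Parameters
    ----------
    design
        DataFrame with one column per covariate plus a binary ``label``
        column (1 = present).
    covariates
        Covariate column names; defaults to all non-label columns.
    """

    def __init__(self, design: pd.DataFrame, covariates=None):
        if covariates is None:
            covariates = [
                c for c in design.columns if c not in ("label", "true_prob")
            ]
        self.covariates = tuple(covariates)
        self.endog = design["label"].to_numpy().astype(int)
        self.exog = design[list(self.covariates)].to_numpy(dtype=float)
        classes = np.unique(self.endog)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(
                "training data must contain both presence (1) and absence "
                f"(0) records; found classes {classes.tolist()}"
            )

    @classmethod
    def from_occurrences(cls, occurrences: pd.DataFrame, bioclim: BioclimGrid,
                         variables=DEFAULT_SDM_VARIABLES) -> "HabitatModel":
        design, n_dropped = extract_covariates(occurrences, bioclim, variables)
        model = cls(design, covariates=variables)
        model.n_dropped = n_dropped
        return model

    def fit(self, n_trees: int = 500, seed: int = 0,
            balanced: bool = False, max_features="sqrt",
            min_samples_leaf: int = 10) -> "HabitatModelResults":
        """Grow the bagged ensemble.

        ``balanced=True`` bootstraps equally from each class (for
        absence-heavy data); the default resamples the full training set.
        ``min_samples_leaf`` floors the leaf size: fully-grown trees
        chase the Bernoulli label noise of probabilistic occurrence
        data, and a modest floor makes the vote fraction track the
        underlying probability of presence much more faithfully without
        hurting separable problems.  Deterministic given the seed.
        """
        rng = np.random.default_rng(seed)
        n = self.endog.size
        idx_pos = np.flatnonzero(self.endog == 1)
        idx_neg = np.flatnonzero(self.endog == 0)
        n_half = min(idx_pos.size, idx_neg.size)

        trees = []
        vote_sum = np.zeros(n)
        oob_count = np.zeros(n, dtype=int)
        for _ in range(n_trees):
            if balanced:
                boot = np.concatenate([
                    rng.choice(idx_pos, n_half, replace=True),
                    rng.choice(idx_neg, n_half, replace=True),
                ])
            else:
                boot = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_features=max_features,
                min_samples_leaf=min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(self.exog[boot], self.endog[boot])
            trees.append(tree)
            oob = np.ones(n, dtype=bool)
            oob[boot] = False
            if oob.any():
                pred = tree.predict(self.exog[oob])
                vote_sum[oob] += pred
                oob_count[oob] += 1

        with np.errstate(invalid="ignore"):
            oob_votes = np.where(oob_count > 0, vote_sum / oob_count, np.nan)
        return HabitatModelResults(
            self, trees, oob_votes,
            metadata={
                "n_trees": n_trees, "seed": seed, "balanced": balanced,
                "max_features": max_features,
                "covariates": list(self.covariates),
                "n_present": int(idx_pos.size), "n_absent": int(idx_neg.size),
            },
        )


class HabitatModelResults:
    """A fitted habitat ensemble: trees, OOB votes and predictions."""

    def __init__(self, model: HabitatModel, trees, oob_votes, metadata):
        self.model = model
        self.trees = trees
        self.oob_votes = np.asarray(oob_votes, dtype=float)
        self.metadata = dict(metadata)

    def oob_auc(self) -> float:
        """AUC of out-of-bag vote fractions against the training labels."""
        ok = ~np.isnan(self.oob_votes)
        return auc(self.oob_votes[ok], self.model.endog[ok])

    def predict_proba(self, X) -> np.ndarray:
        """Vote-fraction probability of presence for covariate rows."""
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.trees:
            votes += tree.predict(X)
        return votes / len(self.trees)

    def predict_surface(self, bioclim: BioclimGrid, period: str = "baseline",
                        ice_mask: RasterGrid | None = None) -> RasterGrid:
        """Probability-of-presence surface on a bioclim grid.

        Nodata cells stay nodata; cells under a truthy ice-mask value are
        forced to nodata before prediction (ice-covered land is treated
        as no habitat information rather than probability zero).
        """
        missing = [v for v in self.model.covariates if v not in bioclim]
        if missing:
            raise KeyError(f"bioclim grid lacks model covariate(s): {missing}")
        template = bioclim.template
        if ice_mask is not None:
            template.require_same_geometry(ice_mask)
        stack = bioclim.stack(self.model.covariates)
        valid = ~np.isnan(stack).any(axis=0)
        if ice_mask is not None:
            valid &= ~(np.nan_to_num(ice_mask.data) > 0)
        out = np.full(template.shape, np.nan)
        if valid.any():
            out[valid] = self.predict_proba(stack[:, valid].T)
        return template.with_data(out, name=f"p_presence_{period}")

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Habitat model (bagged classification trees)",
            "=" * 44,
            f"covariates:   {', '.join(md['covariates'])}",
            f"n records:    {md['n_present'] + md['n_absent']} "
            f"({md['n_present']} present / {md['n_absent']} absent)",
            f"n trees:      {md['n_trees']}   seed: {md['seed']}   "
            f"balanced: {md['balanced']}",
            f"OOB AUC:      {self.oob_auc():.4f}",
        ]
        return "\n".join(lines)
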