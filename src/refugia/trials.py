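"""Provenance-trial designs for common-garden experiments.

A trial is a randomised complete block (RCB) series: provenances (open-
pollinated seed collections, each tagged with its ecological region of
origin) are planted in multi-tree row plots, replicated in blocks within
each of several test sites.  The default design mirrors a typical
boreal-transect aspen trial: 43 provenances from six regions, 5-tree row
plots, 6 blocks, 5 sites; growth is scored at every site while
phenology (bud break, leaf senescence) is scored at a single site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitParams", "TraitSpec", "TrialDesign",
    "expand_design", "default_trial_design", "TABLE1_RESIDUALS",
]


@dataclass(frozen=True)
class TraitParams:
    """Generating parameters of one trait in one region.

    Variances follow the random-effects decomposition of the trial:
    provenance (P), site (S), provenance × site (P×S), block within site
    (B(S)), provenance × block within site (P×B(S)), and the residual —
    the within-plot term that carries within-population genetic variance.
    All on the trait's measurement scale (e.g. m² for height, days² for
    phenology).
    """

    mean: float
    var_prov: float = 0.0
    var_site: float = 0.0
    var_prov_site: float = 0.0
    var_block: float = 0.0
    var_prov_block: float = 0.0
    var_resid: float = 1.0

    def __post_init__(self) -> None:
        for name in ("var_prov", "var_site", "var_prov_site", "var_block",
                     "var_prov_block", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def variances(self, multi_site: bool) -> dict[str, float]:
        if multi_site:
            return {
                "provenance": self.var_prov,
                "site": self.var_site,
                "provenance_x_site": self.var_prov_site,
                "block_in_site": self.var_block,
                "provenance_x_block": self.var_prov_block,
                "residual": self.var_resid,
            }
        return {
            "provenance": self.var_prov,
            "block": self.var_block,
            "provenance_x_block": self.var_prov_block,
            "residual": self.var_resid,
        }


@dataclass(frozen=True)
class TraitSpec:
    """One measured trait: per-region generating parameters and whether
    it is scored at every site or only at the first site."""

    params_by_region: dict[str, TraitParams]
    single_site: bool = False


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a provenance trial.

    ``provenance_regions`` assigns a region label to each provenance
    (its length is the provenance count).
    """

    provenance_regions: tuple[str, ...]
    n_sites: int = 5
    n_blocks: int = 6
    n_trees: int = 5
    traits: dict[str, TraitSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.provenance_regions) < 1:
            raise ValueError("need at least one provenance")
        for name, value in (("n_sites", self.n_sites),
                            ("n_blocks", self.n_blocks),
                            ("n_trees", self.n_trees)):
            if value < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_provenances(self) -> int:
        return len(self.provenance_regions)

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.provenance_regions:
            seen.setdefault(r)
        return tuple(seen)

    def subset_region(self, region: str) -> "TrialDesign":
        """The design restricted to one region's provenances."""
        regions = tuple(r for r in self.provenance_regions if r == region)
        if not regions:
            raise KeyError(f"no provenances from region {region!r}")
        return TrialDesign(
            regions, self.n_sites, self.n_blocks, self.n_trees, self.traits
        )


def expand_design(design: TrialDesign, single_site: bool = False):
    """Expand a design into its record skeleton.

    Returns ``(skeleton, n_records)``: the full provenance × site ×
    block × tree crossing as a DataFrame (region, provenance, site,
    block, tree) and the record count.  ``single_site=True`` restricts
    to the first site (the layout of single-site phenology traits).
    """
    n_sites = 1 if single_site else design.n_sites
    p = design.n_provenances
    idx = pd.MultiIndex.from_product(
        [range(p), range(1, n_sites + 1),
         range(1, design.n_blocks + 1), range(1, design.n_trees + 1)],
        names=["prov_idx", "site", "block", "tree"],
    )
    skeleton = idx.to_frame(index=False)
    skeleton.insert(
        0, "region",
        np.asarray(design.provenance_regions)[skeleton["prov_idx"]],
    )
    skeleton["provenance"] = skeleton.pop("prov_idx") + 1
    skeleton = skeleton[["region", "provenance", "site", "block", "tree"]]
    return skeleton, len(skeleton)


#: Within-population (residual) variance components by region and trait,
#: used as the generator's default generating parameters (height on the
#: measurement scale; bud break and leaf senescence in days²).
TABLE1_RESIDUALS = {
    "BC Northeast": {"height": 0.61, "bud_break": 8.4, "leaf_senescence": 5.2},
    "Northern AB": {"height": 0.71, "bud_break": 8.9, "leaf_senescence": 6.6},
    "AB Foothills": {"height": 0.87, "bud_break": 9.2, "leaf_senescence": 10.3},
    "Central AB": {"height": 0.81, "bud_break": 8.8, "leaf_senescence": 7.5},
    "Saskatchewan": {"height": 0.80, "bud_break": 8.9, "leaf_senescence": 6.2},
    "Minnesota": {"height": 0.94, "bud_break": 13.1, "leaf_senescence": 8.3},
}

#: Provenances per region in the default 43-provenance trial.
_REGION_COUNTS = {
    "BC Northeast": 6, "Northern AB": 7, "AB Foothills": 7,
    "Central AB": 8, "Saskatchewan": 7, "Minnesota": 8,
}

#: Default non-residual generating variances and trait means.
_TRAIT_BASE = {
    "height": dict(mean=8.0, var_prov=0.15, var_site=0.5,
                   var_prov_site=0.05, var_block=0.10, var_prov_block=0.10),
    "bud_break": dict(mean=140.0, var_prov=6.0, var_block=3.0,
                      var_prov_block=3.0),
    "leaf_senescence": dict(mean=270.0, var_prov=5.0, var_block=3.0,
                            var_prov_block=3.0),
}


def default_trial_design() -> TrialDesign:
    """The default 43-provenance, 6-region, 5-site aspen trial design.

    Generating residual variances per region and trait come from the
    within-population variance-component table; the other components are
    fixed realistic defaults (see the methods documentation).
    """
    regions: list[str] = []
    for region, count in _REGION_COUNTS.items():
        regions.extend([region] * count)
    traits = {}
    for trait, base in _TRAIT_BASE.items():
        params = {
            region: TraitParams(
                **base, var_resid=TABLE1_RESIDUALS[region][trait]
            )
            for region in _REGION_COUNTS
        }
        traits[trait] = TraitSpec(params, single_site=trait != "height")
    return TrialDesign(tuple(regions), traits=traits)
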