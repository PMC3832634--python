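"""End-to-end report: scaling tables, limb comparisons, phylogenetic tests.

Reproduces, from any conforming species-means table (and optional tree),
a standard comparative-analysis layout: one RMA scaling table per trait with
departures from geometric similarity, fore/hind common-slope and
common-elevation comparisons, Pagel's-lambda signal and lambda-PGLS
tables under both branch-length treatments, and the angular-acceleration
exponent-composition table.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import constants
from .allometry import common_elevation_test, run_scaling_table
from .exponents import acceleration_limits
from .io import AnalysisConfig, default_groups, load_groups_yaml, read_species_csv
from .null_models import gs_predicted_exponent
from .phylo import (
    Phylogeny,
    fit_lambda_ml,
    normalize_name,
    pgls_lambda_regression,
    read_newick,
    residual_signal_test,
    set_branch_lengths_unity,
)

__all__ = ["run_report", "TRAIT_NULLS"]

logger = logging.getLogger(__name__)

#: geometric-similarity null exponent per trait suffix
TRAIT_NULLS: Dict[str, Fraction] = {
    "length": gs_predicted_exponent("length"),
    "mass": gs_predicted_exponent("mass"),
    "com": gs_predicted_exponent("com_position"),
    "moi": gs_predicted_exponent("moi"),
    "radius": gs_predicted_exponent("radius_of_gyration"),
    "freq": gs_predicted_exponent("natural_frequency"),
}


def _null_for(trait: str) -> float:
    suffix = trait.rsplit("_", 1)[-1]
    try:
        return float(TRAIT_NULLS[suffix])
    except KeyError:
        raise ValueError(
            f"no geometric-similarity null for trait {trait!r}; expected a "
            f"suffix in {sorted(TRAIT_NULLS)}"
        ) from None


def run_report(config: AnalysisConfig) -> Dict[str, pd.DataFrame]:
    """Run the whole pipeline and write its tables under ``config.out_dir``.

    Returns the tables keyed by name; writes each as CSV plus a
    human-readable ``report.txt`` and the resolved config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = read_species_csv(config.data)
    groups = (
        load_groups_yaml(config.groups_file)
        if config.groups_file
        else default_groups(data)
    )
    traits = [t for t in config.traits if t in data.columns]
    skipped = sorted(set(config.traits) - set(traits))
    if skipped:
        logger.warning("traits absent from data, skipped: %s", skipped)

    tables: Dict[str, pd.DataFrame] = {}

    # per-trait RMA scaling tables vs the geometric-similarity null
    scaling_rows: List[pd.DataFrame] = []
    for trait in traits:
        tab = run_scaling_table(data, trait, _null_for(trait), groups=groups)
        tab.insert(0, "trait", trait)
        scaling_rows.append(tab)
    tables["scaling"] = pd.concat(scaling_rows, ignore_index=True)

    # fore vs hind comparisons per trait pair, whole sample
    comp_rows = []
    for suffix in ("length", "mass", "com", "moi", "radius", "freq"):
        fore, hind = f"forelimb_{suffix}", f"hindlimb_{suffix}"
        if fore not in data.columns or hind not in data.columns:
            continue
        x = np.log10(data["body_mass"].to_numpy(dtype=float))
        pair = {
            "fore": (x, np.log10(data[fore].to_numpy(dtype=float))),
            "hind": (x, np.log10(data[hind].to_numpy(dtype=float))),
        }
        cmp_ = common_elevation_test(pair)
        comp_rows.append({
            "trait": suffix,
            "common_slope": cmp_.common_slope,
            "slope_LR": cmp_.common_slope_stat,
            "slope_p": cmp_.common_slope_p,
            "elevation_W": cmp_.elevation_stat,
            "elevation_p": cmp_.elevation_p,
        })
    tables["fore_hind"] = pd.DataFrame(comp_rows)

    # phylogenetic signal and lambda-PGLS, both branch-length modes
    if config.tree:
        phy_dt = read_newick(config.tree)
        modes = {
            "divergence_times": phy_dt,
            "unity": set_branch_lengths_unity(phy_dt),
        }
        keys = data["species"].map(normalize_name)
        phylo_rows = []
        for mode_name, phy in modes.items():
            if config.branch_mode != "both" and mode_name != config.branch_mode:
                continue
            logm = dict(zip(keys, np.log10(data["body_mass"].astype(float))))
            for trait in traits:
                vals = dict(zip(keys, np.log10(data[trait].astype(float))))
                sig = fit_lambda_ml(vals, phy)
                res = residual_signal_test(vals, logm, phy)
                fit = pgls_lambda_regression(vals, logm, phy)
                phylo_rows.append({
                    "mode": mode_name, "trait": trait,
                    "lambda_trait": sig.lam,
                    "lambda_trait_ci_low": sig.ci[0],
                    "lambda_trait_ci_high": sig.ci[1],
                    "lambda_resid": res.lam,
                    "lambda_resid_ci_low": res.ci[0],
                    "lambda_resid_ci_high": res.ci[1],
                    "pgls_slope": fit.slope,
                    "pgls_slope_ci_low": fit.slope_ci[0],
                    "pgls_slope_ci_high": fit.slope_ci[1],
                    "pgls_lambda": fit.lambda_estimate.lam,
                })
        tables["phylo"] = pd.DataFrame(phylo_rows)

    # angular-acceleration composition from the versioned constants
    accel_rows = []
    for limb, arm, moi, force in (
        ("hind", constants.MOMENT_ARM_HINDLIMB, constants.MOI_HINDLIMB_LIMITS,
         constants.MUSCLE_FORCE),
        ("fore", constants.MOMENT_ARM_FORELIMB, constants.MOI_FORELIMB_LIMITS,
         constants.MUSCLE_FORCE_FORELIMB),
    ):
        acc = acceleration_limits(force, arm, moi, limb=limb)
        accel_rows.append({
            "limb": limb, "exponent": acc.exponent,
            "limit_lower": acc.limit_lower, "limit_upper": acc.limit_upper,
        })
    tables["acceleration"] = pd.DataFrame(accel_rows)

    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.csv", index=False)
    config.dump(out / "resolved_config.yaml")
    with open(out / "report.txt", "w") as fh:
        for name, tab in tables.items():
            fh.write(f"== {name} ==\n")
            fh.write(tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
            fh.write("\n\n")
    logger.info("report written to %s", out)
    return tables
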