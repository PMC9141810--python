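"""File-based fitting pipeline: read statistics, fit, write model + fdr table.

This is the plumbing behind the command-line interface; everything
scientific lives in :mod:`ultrafdr.entropic_fit`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import entropic_fit as ef
from .distributions import pvalue, quantile, statistic_to_angle
from .families import FamilySpec, spec_from_name

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_statistics", "run_fit"]

_PRECISION = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one fitting run."""

    input_path: str
    family: str
    nu1: float | None = None
    nu2: float | None = None
    order: int = 8
    route: str | None = None
    prior_domain: tuple[float, float] | None = None
    bins: int = 200
    seed: int = 0
    output_dir: str = "."
    column: str = "statistic"
    statistic_scale: str = "conventional"  # or "angle" for t/F already in x
    upper_tail: bool = False               # pvalue column is upper-tail

    spec: FamilySpec = field(init=False)

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        self.spec = spec_from_name(self.family, self.nu1, self.nu2)


def read_statistics(path, config: RunConfig) -> np.ndarray:
    """Read a TSV/CSV column of statistics (or p-values) as family-variable values.

    A ``pvalue`` column is converted through the central quantile (upper-tail
    p-values are flipped first when ``config.upper_tail``).  Non-numeric or
    non-finite rows are dropped with their row numbers logged.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path}: empty input")
    if config.column in df.columns:
        raw = pd.to_numeric(df[config.column], errors="coerce").to_numpy()
        is_p = False
    elif "pvalue" in df.columns:
        raw = pd.to_numeric(df["pvalue"], errors="coerce").to_numpy()
        is_p = True
    else:
        raise ValueError(f"{path}: no '{config.column}' or 'pvalue' column "
                         f"(found {list(df.columns)})")
    bad = ~np.isfinite(raw)
    if bad.any():
        rows = np.flatnonzero(bad) + 2  # 1-based incl. header
        logger.warning("%s: dropped %d non-numeric rows (e.g. lines %s)",
                       path, bad.sum(), rows[:5].tolist())
    values = raw[~bad]
    if values.size == 0:
        raise ValueError(f"{path}: no numeric values in input")
    if is_p:
        p = 1.0 - values if config.upper_tail else values
        return np.asarray(quantile(config.spec, p))
    if config.statistic_scale == "conventional":
        return np.asarray(statistic_to_angle(config.spec, values))
    return values


def run_fit(config: RunConfig) -> dict:
    """Fit the model and write model.json, fdr_table.tsv and diagnostics.json.

    Returns the diagnostics dictionary.  Raises on non-convergence (the CLI
    maps that to a nonzero exit code after writing a diagnostics file).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    values = read_statistics(config.input_path, config)
    route = ef.Route(config.route) if config.route else None
    model = ef.fit_model(values, config.spec, order=config.order, route=route,
                         prior_domain=config.prior_domain)

    (outdir / "model.json").write_text(ef.model_to_json(model))

    p = np.asarray(pvalue(config.spec, values))
    bf = np.asarray(ef.bayes_factor(model, values, clip=True))
    table = pd.DataFrame({"statistic": values, "p": p, "BF": bf,
                          "fdr": 1.0 / (1.0 + bf)})
    table.to_csv(outdir / "fdr_table.tsv", sep="\t", index=False,
                 float_format=_PRECISION)

    kl_by_order = {}
    for n in range(1, config.order + 1):
        sub = ef.BayesFactorModel(config.spec, model.route, model.beta.truncated(n),
                                  model.prior)
        if model.route is ef.Route.PRIOR:
            sub_prior = ef.fit_gibbs_prior(model.beta.truncated(n),
                                           prior_domain=model.prior.dual.prior_domain)
            sub = ef.BayesFactorModel(config.spec, model.route,
                                      model.beta.truncated(n), sub_prior)
        kl_by_order[n] = ef.model_fit_kl(values, sub, bins=config.bins)

    diagnostics = {
        "n_used": model.beta.n_samples,
        "n_rejected": model.beta.n_rejected,
        "beta": model.beta.beta.tolist(),
        "beta_se": model.beta.se.tolist(),
        "lambda": model.prior.dual.lam.tolist() if model.prior else None,
        "moment_residual": None if model.prior is None else model.prior.moment_residual,
        "clip_fraction": model.clip_fraction,
        "kl_by_order": kl_by_order,
        "route": model.route.value,
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    return diagnostics
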