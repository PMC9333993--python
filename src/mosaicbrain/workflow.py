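"""Data ingestion, species-level summaries, unit conversion, QC, and the
pipeline runner.

Conventions: trait tables are delimited text with one row per individual and
columns ``species`` (required), optionally ``individual`` and ``group``
(phenotype label), ``body`` (mass, g), ``brain`` (total brain volume, mm^3)
and/or ``brain_mass`` (g), and region volumes (mm^3) named OB, TEL, HB, OT,
TS, CB, RoB. All allometric analyses run on base-10 logarithms of
species-mean traits; intraspecific standard errors accompany the means, with
singleton species receiving the mean SE across multi-individual species
(flagged as imputed). Volumes are stored in mm^3 and converted to cm^3
internally before the density-based mass conversion.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phylo import Phylogeny, prune_tree, read_newick

__all__ = [
    "REQUIRED_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "load_trait_table",
    "write_trait_table",
    "species_summary",
    "volume_to_mass",
    "coefficient_of_variation",
    "log10_columns",
    "region_vs_rest_columns",
    "run_pipeline",
]

logger = logging.getLogger("mosaicbrain")

REQUIRED_COLUMNS = ("species",)
MEASUREMENT_COLUMNS = ("body", "brain", "brain_mass", "OB", "TEL", "HB", "OT", "TS", "CB", "RoB")
FIXED_BRAIN_DENSITY = 1.32  # g/cm^3, mean density of fixed brain tissue


class SchemaError(ValueError):
    """A required column is absent from a trait table."""


def load_trait_table(
    path,
    sep: str | None = None,
    phenotype_vocabulary: list[str] | None = None,
) -> pd.DataFrame:
    """Read and validate a delimited trait table.

    Unknown columns are preserved but ignored downstream. Measurement
    columns must be non-negative; violations raise with the row index.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' missing from {path}")
    if df["species"].isna().any() or (df["species"].astype(str).str.len() == 0).any():
        raise ValueError("empty species labels")
    for col in MEASUREMENT_COLUMNS:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.notna() & (vals < 0)]
            if len(bad):
                raise ValueError(
                    f"negative measurement in column '{col}' at row(s) {list(bad)}"
                )
            df[col] = vals
    if phenotype_vocabulary is not None and "group" in df.columns:
        unknown = set(df["group"].dropna().astype(str)) - set(phenotype_vocabulary)
        if unknown:
            raise ValueError(f"phenotype labels outside vocabulary: {sorted(unknown)}")
    return df


def write_trait_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a trait table losslessly (15 significant digits)."""
    df.to_csv(path, sep=sep, index=False, float_format="%.15g")


def species_summary(
    table: pd.DataFrame, traits: list[str] | None = None
) -> pd.DataFrame:
    """Per-species trait means, standard errors, and individual counts.

    SE is the standard error of the mean (sample SD / sqrt(n)). Species with
    a single individual receive, per trait, the mean SE across
    multi-individual species, flagged in ``se_imputed``; if every species is
    a singleton the imputation is impossible and an error is raised.
    """
    if traits is None:
        traits = [c for c in MEASUREMENT_COLUMNS if c in table.columns]
    if not traits:
        raise ValueError("no measurement columns to summarize")
    g = table.groupby("species")
    out = pd.DataFrame({"n_individuals": g.size()})
    if "group" in table.columns:
        out["group"] = g["group"].first()
    for c in traits:
        out[f"{c}_mean"] = g[c].mean()
        sd = g[c].std(ddof=1)
        out[f"{c}_se"] = sd / np.sqrt(out["n_individuals"])
    multi = out["n_individuals"] > 1
    if not multi.any() and (out["n_individuals"] == 1).any():
        raise ValueError(
            "all species are singletons: intraspecific SE cannot be imputed"
        )
    out["se_imputed"] = ~multi
    for c in traits:
        fill = out.loc[multi, f"{c}_se"].mean()
        out.loc[~multi, f"{c}_se"] = fill
    return out


def volume_to_mass(volume_cm3, density: float = FIXED_BRAIN_DENSITY):
    """Convert tissue volume (cm^3) to mass (g) via fixed-tissue density."""
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volume must be >= 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    out = v * density
    return float(out) if np.isscalar(volume_cm3) else out


def coefficient_of_variation(repeats) -> float:
    """CV of repeated measurements, as a percentage (sample SD / mean)."""
    v = np.asarray(repeats, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def log10_columns(
    summary: pd.DataFrame, traits: list[str], suffix: str = "_mean"
) -> pd.DataFrame:
    """log10-transform species-mean trait columns into ``log_<trait>``."""
    out = summary.copy()
    for c in traits:
        col = f"{c}{suffix}" if f"{c}{suffix}" in out.columns else c
        vals = out[col].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"non-positive values in '{col}' cannot be log10ed")
        out[f"log_{c}"] = np.log10(vals)
    return out


def region_vs_rest_columns(
    summary: pd.DataFrame,
    regions: list[str],
    total: str = "brain",
    suffix: str = "_mean",
) -> pd.DataFrame:
    """Derived columns: total brain minus each focal region (natural scale)."""
    out = summary.copy()
    tot = out[f"{total}{suffix}" if f"{total}{suffix}" in out.columns else total]
    for r in regions:
        col = f"{r}{suffix}" if f"{r}{suffix}" in out.columns else r
        rest = tot - out[col]
        if (rest <= 0).any():
            raise ValueError(f"region '{r}' exceeds total '{total}' for some species")
        out[f"rest_{r}"] = rest
    return out


# ---------------------------------------------------------------------------
# pipeline


KNOWN_STAGES = (
    "qc",
    "summary",
    "grade-ancova",
    "region-ancova",
    "region-matrix",
    "ppca",
    "pfda",
    "pc-models",
    "rjmcmc",
    "stepstone",
)

# stages that require the output of another stage
STAGE_DEPS = {
    "grade-ancova": ["summary"],
    "region-ancova": ["summary"],
    "region-matrix": ["summary"],
    "ppca": ["summary"],
    "pfda": ["summary"],
    "pc-models": ["ppca"],
    "rjmcmc": ["summary"],
    "stepstone": ["summary"],
}


def _config_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _species_log_table(summary: pd.DataFrame, cfg: dict) -> pd.DataFrame:
    traits = [c for c in MEASUREMENT_COLUMNS if f"{c}_mean" in summary.columns]
    return log10_columns(summary, traits)


def run_pipeline(config_path) -> dict:
    """Execute pipeline stages in dependency order from a YAML config.

    The config names the tree, the trait table, the output directory, the
    seed, and the requested stages; every run writes a provenance record
    (inputs, config hash, seed, package version) sufficient to re-run
    deterministic stages bit-identically.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    stages = list(cfg.get("stages", []))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; known: {KNOWN_STAGES}")
    # resolve dependencies up front, before any computation
    ordered: list[str] = []

    def need(stage: str) -> None:
        for dep in STAGE_DEPS.get(stage, []):
            need(dep)
        if stage not in ordered:
            ordered.append(stage)

    for s in stages:
        need(s)
    outdir = Path(cfg.get("outdir", "results"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    table = load_trait_table(cfg["table"]) if "table" in cfg else None
    tree = read_newick(Path(cfg["tree"]).read_text()) if "tree" in cfg else None
    if table is None:
        raise ValueError("config must name a trait table")
    logger.info("pipeline stages: %s", ordered)

    results: dict = {}
    summary = None
    species_log = None
    ppca_res = None

    for stage in ordered:
        if stage == "qc":
            rows = []
            for c in [c for c in MEASUREMENT_COLUMNS if c in table.columns]:
                for sp, grp in table.groupby("species")[c]:
                    vals = grp.dropna()
                    if len(vals) >= 2 and vals.mean() != 0:
                        rows.append(
                            {
                                "species": sp,
                                "trait": c,
                                "n": len(vals),
                                "cv_percent": coefficient_of_variation(vals),
                            }
                        )
            qc = pd.DataFrame(rows, columns=["species", "trait", "n", "cv_percent"])
            qc.to_csv(outdir / "qc_cv.tsv", sep="\t", index=False)
            results["qc"] = qc
        elif stage == "summary":
            summary = species_summary(table)
            species_log = _species_log_table(summary, cfg)
            if tree is not None:
                keep = [s for s in tree.tip_labels if s in set(summary.index)]
                missing = sorted(set(summary.index) - set(tree.tip_labels))
                if missing:
                    logger.info("dropping %d species absent from tree", len(missing))
                    summary = summary.loc[keep]
                    species_log = species_log.loc[keep]
                if len(keep) < tree.n_tips:
                    tree = prune_tree(tree, keep)
            summary.to_csv(outdir / "species_summary.tsv", sep="\t")
            results["summary"] = summary
        elif stage in ("grade-ancova", "region-ancova", "region-matrix"):
            from .pgls import ModelSpec, ancova_groups

            if "group" not in species_log.columns:
                raise ValueError(f"stage {stage} needs a 'group' column")
            pairs: list[tuple[str, str]] = []
            if stage == "grade-ancova":
                pairs = [("log_brain_mass" if "log_brain_mass" in species_log else "log_brain", "log_body")]
            elif stage == "region-ancova":
                regions = [r for r in ("OB", "TEL", "HB", "OT", "TS", "CB", "RoB") if f"log_{r}" in species_log.columns]
                pairs = [(f"log_{r}", "log_brain") for r in regions]
            else:
                regions = [r for r in ("OB", "TEL", "HB", "OT", "TS", "CB", "RoB") if f"log_{r}" in species_log.columns]
                pairs = [
                    (f"log_{a}", f"log_{b}")
                    for a in regions
                    for b in regions
                    if a != b
                ]
            rows = []
            for resp, cov in pairs:
                res = ancova_groups(
                    ModelSpec(resp, (cov,), "group"), species_log, tree
                )
                rows.append(
                    {
                        "response": resp,
                        "covariate": cov,
                        "lambda": res.lam,
                        "slope_p": res.slope_p,
                        "intercept_p": res.intercept_p,
                        "posthoc_performed": bool(
                            res.posthoc and res.posthoc.performed
                        ),
                    }
                )
            tab = pd.DataFrame(rows)
            tab.to_csv(outdir / f"{stage}.tsv", sep="\t", index=False)
            results[stage] = tab
        elif stage == "ppca":
            from .multivar import ppca_fit, ppca_project, zscore_normalize

            regions = [f"log_{r}" for r in ("OB", "TEL", "HB", "OT", "TS", "CB", "RoB") if f"log_{r}" in species_log.columns]
            traits = species_log[regions]
            if cfg.get("ppca_zscore", False):
                traits = zscore_normalize(traits)
            ppca_res = ppca_fit(traits, tree)
            ppca_res.eigenvectors.to_csv(outdir / "ppca_loadings.tsv", sep="\t")
            ppca_res.scores.to_csv(outdir / "ppca_scores.tsv", sep="\t")
            pd.Series(
                ppca_res.percent_variance,
                index=ppca_res.eigenvectors.columns,
                name="percent_variance",
            ).to_csv(outdir / "ppca_percent_variance.tsv", sep="\t")
            results["ppca"] = ppca_res
        elif stage == "pfda":
            from .multivar import pfda_fit_predict, pfda_optimize_lambda
            from .pgls import ModelSpec, fit_pgls

            regions = [r for r in ("OB", "TEL", "HB", "OT", "TS", "CB", "RoB") if f"log_{r}" in species_log.columns]
            # default input: residuals of per-region PGLS against total brain
            resid = {}
            for r in regions:
                f = fit_pgls(
                    ModelSpec(f"log_{r}", ("log_brain",)), species_log, tree, lam="ML"
                )
                resid[r] = f.resid
            R = pd.DataFrame(resid)
            groups = species_log.loc[R.index, "group"]
            lam_star, curve = pfda_optimize_lambda(R, groups, tree)
            fda = pfda_fit_predict(R, groups, tree, lam_star)
            curve.to_csv(outdir / "pfda_lambda_curve.tsv", sep="\t", index=False)
            fda.coefficients.to_csv(outdir / "pfda_coefficients.tsv", sep="\t")
            fda.confusion.to_csv(outdir / "pfda_confusion.tsv", sep="\t")
            results["pfda"] = fda
        elif stage == "pc-models":
            from .pgls import ModelSpec, candidate_model_selection

            scores = ppca_res.scores
            dat = species_log.join(scores)
            tables = {}
            for pc in [c for c in scores.columns[:4]]:
                covs: list[tuple[str, ...]] = (
                    [("log_body",)] if pc == "PC1" else [("log_body", "log_brain")]
                )
                cands = [ModelSpec(pc, covs[0])]
                if "group" in dat.columns:
                    cands.append(ModelSpec(pc, covs[0], "group"))
                tab, _ = candidate_model_selection(cands, dat.dropna(subset=[*covs[0]]), tree)
                tab.to_csv(outdir / f"pc_models_{pc}.tsv", sep="\t", index=False)
                tables[pc] = tab
            results["pc-models"] = tables
        elif stage == "rjmcmc":
            from .oumodel import ChainConfig, PriorSpec, rjmcmc_run, summarize_posterior

            resp = "log_brain_mass" if "log_brain_mass" in species_log else "log_brain"
            x = species_log["log_body"]
            y = species_log[resp]
            se_col = resp.replace("log_", "") + "_se"
            mean_col = resp.replace("log_", "") + "_mean"
            # delta-method SE on the log10 scale
            se = (
                summary[se_col] / (summary[mean_col] * np.log(10))
                if se_col in summary.columns
                else pd.Series(0.0, index=summary.index)
            )
            prior = PriorSpec.from_tree(tree)
            mc = cfg.get("rjmcmc", {})
            config = ChainConfig(
                iterations=int(mc.get("iterations", 50_000)),
                thin=int(mc.get("thin", 50)),
                priming=int(mc.get("priming", 2_000)),
                n_chains=int(mc.get("chains", 2)),
                seed=seed,
            )
            chains = rjmcmc_run(tree, x, y, se, prior, config)
            for i, ch in enumerate(chains):
                ch.to_dataframe().to_csv(
                    outdir / f"rjmcmc_chain{i + 1}.tsv", sep="\t", index=False
                )
            summ = summarize_posterior(chains, tree)
            summ.branch_prob.to_csv(outdir / "rjmcmc_branch_prob.tsv", sep="\t")
            summ.shifts.to_csv(outdir / "rjmcmc_shifts.tsv", sep="\t", index=False)
            summ.params.to_csv(outdir / "rjmcmc_params.tsv", sep="\t")
            results["rjmcmc"] = summ
        elif stage == "stepstone":
            from .oumodel import (
                PriorSpec,
                bayes_factor_2ln,
                fixed_shift_model,
                stepping_stone_logml,
            )

            resp = "log_brain_mass" if "log_brain_mass" in species_log else "log_brain"
            x = species_log["log_body"]
            y = species_log[resp]
            se = pd.Series(0.0, index=species_log.index)
            prior = PriorSpec.from_tree(tree)
            ss = cfg.get("stepstone", {})
            branches = [int(b) for b in ss.get("branches", [])]
            models = {
                "shift": fixed_shift_model(tree, branches),
                "null": fixed_shift_model(tree, []),
            }
            out = {}
            for name, model in models.items():
                out[name] = stepping_stone_logml(
                    model,
                    tree,
                    x,
                    y,
                    se,
                    prior,
                    steps=int(ss.get("steps", 50)),
                    iterations_per_step=int(ss.get("iterations_per_step", 2000)),
                    seed=seed,
                ).logml
            bf = bayes_factor_2ln(out["shift"], out["null"])
            tab = pd.DataFrame(
                {"model": list(out), "logml": list(out.values())}
            )
            tab.to_csv(outdir / "stepstone_logml.tsv", sep="\t", index=False)
            (outdir / "stepstone_2lnBF.txt").write_text(f"{bf:.6g}\n")
            results["stepstone"] = {"logml": out, "2lnBF": bf}

    provenance = {
        "package_version": __version__,
        "config": str(config_path),
        "config_sha256_16": _config_hash(config_path),
        "seed": seed,
        "stages_run": ordered,
        "inputs": {k: str(cfg[k]) for k in ("tree", "table") if k in cfg},
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    results["provenance"] = provenance
    return results
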