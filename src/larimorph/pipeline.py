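"""End-to-end analysis driver: align data to tree, run every stage, serialize.

The stages mirror the study design: (1) morphometric derivation; (2) mantle
darkness regressed on standardized wing loading + absolute latitude under
NP/BM/OU/lambda with LRT model selection and OU half-life; (3) wingtip
black proportion under the phylogenetic logit-beta model with ratio and
baseline-prediction summaries; (4) BM ancestral-state reconstruction of
mantle darkness; (5) aspect-ratio OLS and the mantle-wingtip correlation;
(6) the simulate-and-refit adequacy check.  Each stage is independently
toggleable and failures are recorded per stage rather than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adequacy import run_adequacy
from .asr import annotated_newick, asr_bm
from .errors import NameMatchError
from .morphometrics import derive_morphology, read_species_csv, write_species_csv
from .pgls import fit_model, half_life, lrt, ols_fit, pearson
from .phylo import Phylogeny, normalize_label
from .phylo_beta import fit_phylo_beta, predict_proportion, quantile_residuals, squeeze
from .synthetic_data import GeneratorConfig, simulate_species_table, simulate_tree

log = logging.getLogger("larimorph")

MANTLE_COEF_NAMES = ["intercept", "wing_loading_std", "abs_latitude"]


@dataclass
class PipelineConfig:
    species_csv: str = "species.csv"
    tree_newick: str = "tree.nwk"
    out_dir: str = "larimorph_out"
    seed: int = 0
    run_mantle_pgls: bool = True
    run_wingtip_beta: bool = True
    run_aspect_ols: bool = True
    run_asr: bool = True
    run_adequacy: bool = False
    adequacy_reps: int = 500
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stamp(df: pd.DataFrame, cfg_hash: str) -> pd.DataFrame:
    df = df.copy()
    df["package_version"] = __version__
    df["config_hash"] = cfg_hash
    return df


def load_inputs(config: PipelineConfig):
    records = read_species_csv(config.species_csv)
    with open(config.tree_newick) as fh:
        tree = Phylogeny.from_newick(fh.read())
    return records, tree


def align_to_tree(df: pd.DataFrame, tree: Phylogeny) -> tuple[pd.DataFrame, Phylogeny]:
    """Match table species to tree tips (exact after underscore/space
    normalization), pruning the tree to the table when it has extra tips.

    Raises :class:`NameMatchError` listing any unmatched names.
    """
    names = [normalize_label(s) for s in df["species"]]
    tipset = set(tree.tip_labels)
    missing_in_tree = [n for n in names if n not in tipset]
    if missing_in_tree:
        raise NameMatchError(missing_in_tree=missing_in_tree)
    sub = tree if set(names) == tipset else tree.prune(names)
    order = {lab: i for i, lab in enumerate(sub.tip_labels)}
    df = df.copy()
    df["_species_norm"] = names
    df = df.sort_values("_species_norm", key=lambda s: s.map(order)).drop(columns="_species_norm")
    return df.reset_index(drop=True), sub


def mantle_pgls_stage(morph: pd.DataFrame, tree: Phylogeny, cfg_hash: str = "") -> dict:
    """Four-model comparison of mantle darkness ~ wing loading + |latitude|."""
    from .morphometrics import z_standardize

    data = morph.dropna(subset=["mantle_kgs"]).reset_index(drop=True)
    data, sub = align_to_tree(data, tree)
    # standardize on the per-analysis complete set
    wl_std = z_standardize(data["wing_loading"].to_numpy())
    X = np.column_stack([np.ones(len(data)), wl_std, data["abs_latitude"].to_numpy()])
    y = data["mantle_kgs"].to_numpy()

    fits = {m: fit_model(sub, y, X, m, coef_names=MANTLE_COEF_NAMES)
            for m in ("OU", "LAMBDA", "NP", "BM")}
    lrts = {
        "OU_vs_NP": lrt(fits["NP"], fits["OU"]),
        "OU_vs_BM": lrt(fits["BM"], fits["OU"]),
        "LAMBDA_vs_NP": lrt(fits["NP"], fits["LAMBDA"]),
        "LAMBDA_vs_BM": lrt(fits["BM"], fits["LAMBDA"]),
    }
    hl = half_life(fits["OU"].param)
    assert abs(hl - math.log(2.0) / fits["OU"].param) < 1e-12  # internal consistency

    rows = []
    for m, fit in fits.items():
        for cn, b, se, p in zip(fit.coef_names, fit.beta, fit.se, fit.p_value):
            rows.append(
                {
                    "model": m,
                    "coefficient": cn,
                    "estimate": round(float(b), 2),
                    "se": round(float(se), 2),
                    "p_value": round(float(p), 3),
                    "sigma2": round(float(fit.sigma2), 2),
                    "param_name": fit.param_name or "",
                    "param": "" if fit.param is None else round(float(fit.param), 2),
                    "loglik": round(float(fit.loglik), 2),
                    "aic": round(float(fit.aic), 2),
                }
            )
    table = _stamp(pd.DataFrame(rows), cfg_hash)
    return {
        "fits": fits,
        "lrts": lrts,
        "half_life": hl,
        "table": table,
        "n": int(len(data)),
        "meta": {
            "models": {m: f.to_dict() for m, f in fits.items()},
            "lrts": {k: {"statistic": v.statistic, "df": v.df, "p_value": v.p_value}
                     for k, v in lrts.items()},
            "half_life": hl,
        },
    }


def wingtip_beta_stage(morph: pd.DataFrame, tree: Phylogeny, seed: int = 0,
                       cfg_hash: str = "") -> dict:
    """Phylogenetic logit-beta regression of wingtip black proportion."""
    from .morphometrics import z_standardize

    data = morph.dropna(subset=["wingtip_black"]).reset_index(drop=True)
    data, sub = align_to_tree(data, tree)
    wl_std = z_standardize(data["wing_loading"].to_numpy())
    X = np.column_stack([np.ones(len(data)), wl_std, data["abs_latitude"].to_numpy()])
    y = squeeze(data["wingtip_black"].to_numpy())
    C = sub.correlation_matrix()
    fit = fit_phylo_beta(X, y, C, coef_names=MANTLE_COEF_NAMES)
    resid = quantile_residuals(fit, n_sim=250, seed=seed)
    preds = {f"wl{k}_lat0": predict_proportion(fit, float(k), 0.0) for k in (0, 1, 2)}

    rows = []
    for cn, b, se, z, p in zip(fit.coef_names, fit.beta, fit.se, fit.z_stat, fit.p_value):
        ratio = float(np.exp(b))
        assert abs(ratio - math.exp(b)) < 1e-12  # ratio column is exp(estimate)
        rows.append(
            {
                "coefficient": cn,
                "estimate": round(float(b), 2),
                "se": round(float(se), 2),
                "ratio": round(ratio, 2),
                "z": round(float(z), 2),
                "p_value": round(float(p), 3),
            }
        )
    table = _stamp(pd.DataFrame(rows), cfg_hash)
    return {
        "fit": fit,
        "table": table,
        "predictions": preds,
        "residual_ks_p": resid.ks_p_value,
        "n": int(len(data)),
        "meta": {
            "fit": fit.to_dict(),
            "baseline_predictions": preds,
            "residual_ks_p": resid.ks_p_value,
        },
    }


def aspect_ols_stage(morph: pd.DataFrame) -> dict:
    """OLS of aspect ratio on standardized wing loading + trait correlation."""
    res = ols_fit(morph["wing_loading_std"].to_numpy(), morph["aspect_ratio"].to_numpy())
    both = morph.dropna(subset=["mantle_kgs", "wingtip_black"])
    corr = pearson(both["mantle_kgs"].to_numpy(), both["wingtip_black"].to_numpy())
    return {
        "slope": res.slope,
        "se": res.se,
        "r2": res.r2,
        "p_value": res.p_value,
        "mantle_wingtip_correlation": corr,
        "meta": {
            "aspect_ratio_ols": {
                "slope": res.slope, "se": res.se, "r2": res.r2, "p_value": res.p_value
            },
            "mantle_wingtip_correlation": corr,
        },
    }


def asr_stage(morph: pd.DataFrame, tree: Phylogeny, cfg_hash: str = "") -> dict:
    data = morph.dropna(subset=["mantle_kgs"]).reset_index(drop=True)
    data, sub = align_to_tree(data, tree)
    tip_values = dict(zip(data["species"].map(normalize_label), data["mantle_kgs"]))
    asr = asr_bm(sub, tip_values)
    return {
        "asr": asr,
        "states": _stamp(asr.states_frame(), cfg_hash),
        "newick": annotated_newick(sub, asr),
        "meta": {"n_internal": len(asr.node_states)},
    }


def adequacy_stage(morph: pd.DataFrame, tree: Phylogeny, n_reps: int, seed: int,
                   cfg_hash: str = "") -> dict:
    from .morphometrics import z_standardize

    data = morph.dropna(subset=["mantle_kgs"]).reset_index(drop=True)
    data, sub = align_to_tree(data, tree)
    wl_std = z_standardize(data["wing_loading"].to_numpy())
    X = np.column_stack([np.ones(len(data)), wl_std, data["abs_latitude"].to_numpy()])
    y = data["mantle_kgs"].to_numpy()
    bm = fit_model(sub, y, X, "BM", coef_names=MANTLE_COEF_NAMES)
    ou = fit_model(sub, y, X, "OU", coef_names=MANTLE_COEF_NAMES)
    result = run_adequacy(sub, X, bm, ou, n_reps=n_reps, seed=seed)
    return {"result": result, "table": _stamp(result.to_frame(), cfg_hash),
            "meta": result.to_dict()}


def run_report(config: PipelineConfig) -> dict:
    """Run every enabled stage, tolerating per-stage failures.

    Returns {"stages": {name: {"status", "meta"/"error"}}, ...} and, as a
    side effect of the cli wrapper, writes the CSV/JSON outputs.
    """
    records, tree = load_inputs(config)
    morph = derive_morphology(records)
    cfg_hash = config.hash()
    report = {
        "package_version": __version__,
        "config_hash": cfg_hash,
        "seed": config.seed,
        "stages": {},
    }
    artifacts = {}

    stages = []
    if config.run_mantle_pgls:
        stages.append(("mantle_pgls", lambda: mantle_pgls_stage(morph, tree, cfg_hash)))
    if config.run_wingtip_beta:
        stages.append(("wingtip_beta",
                       lambda: wingtip_beta_stage(morph, tree, config.seed, cfg_hash)))
    if config.run_aspect_ols:
        stages.append(("aspect_ols", lambda: aspect_ols_stage(morph)))
    if config.run_asr:
        stages.append(("asr", lambda: asr_stage(morph, tree, cfg_hash)))
    if config.run_adequacy:
        stages.append(("adequacy",
                       lambda: adequacy_stage(morph, tree, config.adequacy_reps,
                                              config.seed, cfg_hash)))

    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            out = fn()
        except NameMatchError:
            raise  # configuration error: surface immediately
        except Exception as exc:  # pragma: no cover - defensive per-stage isolation
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            continue
        dt = time.perf_counter() - t0
        log.info("stage %s finished in %.2f s", name, dt)
        report["stages"][name] = {"status": "ok", "seconds": round(dt, 3),
                                  "meta": out["meta"]}
        artifacts[name] = out

    report["_artifacts"] = artifacts
    report["_morphology"] = _stamp(morph, cfg_hash)
    return report


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = report.pop("_artifacts", {})
    morph = report.pop("_morphology", None)
    if morph is not None:
        morph.to_csv(out / "derived_morphology.csv", index=False)
    if "mantle_pgls" in art:
        art["mantle_pgls"]["table"].to_csv(out / "mantle_model_comparison.csv", index=False)
    if "wingtip_beta" in art:
        art["wingtip_beta"]["table"].to_csv(out / "wingtip_beta.csv", index=False)
    if "asr" in art:
        art["asr"]["states"].to_csv(out / "asr_states.csv", index=False)
        (out / "asr_annotated.nwk").write_text(art["asr"]["newick"] + "\n")
    if "adequacy" in art:
        art["adequacy"]["table"].to_csv(out / "adequacy_sims.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def simulate_fixture(config: PipelineConfig) -> None:
    """Write a synthetic species CSV + Newick pair at the configured paths."""
    gen = GeneratorConfig(seed=config.seed, **config.generator)
    tree = simulate_tree(gen.n_species, gen.tree_height, seed=gen.seed)
    records = simulate_species_table(tree, gen)
    Path(config.species_csv).parent.mkdir(parents=True, exist_ok=True)
    write_species_csv(records, config.species_csv)
    Path(config.tree_newick).parent.mkdir(parents=True, exist_ok=True)
    Path(config.tree_newick).write_text(tree.to_newick())


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO if verbose else logging.WARNING)
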