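"""End-to-end orchestration: matrix -> search -> consensus -> calibration ->
body-size prediction -> binning -> ancestral states -> reports.

Each stage reads and writes standard formats (TNT/Newick/CSV) so stages are
independently runnable; a run manifest records package versions, the master
seed, the effective paper-gap conventions (log base, lambda mode, bin
edges), and SHA-256 hashes of all inputs and outputs.  The pipeline is a
pure function of (inputs, config): identical bytes in, identical bytes out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from . import allometry, chronology, io_formats, parsimony, size_evolution

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str) -> None:
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    matrix_path: str
    ages_path: str
    extant_path: str
    fossil_path: str
    out_dir: str
    seed: int
    scaffold_path: str | None = None
    tree_path: str | None = None  # precomputed tree: bypasses the search stage
    osmo_path: str | None = None
    outgroup: str | None = None
    n_replicates: int = 5
    rearrangement: str = "SPR"
    max_trees_retained: int = 50
    min_branch: float = 5.0
    tip_age_rule: str = "FAD"
    mcmc_iter: int = 10_000
    mcmc_burn_in: int = 1_000
    mcmc_thin: int = 10
    bin_width_cm: float = 50.0

    def __post_init__(self) -> None:
        for attr in ("matrix_path", "ages_path", "extant_path", "fossil_path"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise PipelineError("config", "missing_input", f"{attr}: {p} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def node_state_table(tree: dendropy.Tree, asr: dict, state_names=None) -> pd.DataFrame:
    rows = []
    for i, nd in enumerate(tree.preorder_node_iter()):
        tips = sorted(
            (lf.taxon.label if lf.taxon else lf.label) for lf in nd.leaf_iter()
        )
        states = sorted(asr[nd])
        if state_names is not None:
            states = [state_names[s] for s in states]
        rows.append(
            {
                "node_id": f"N{i}",
                "n_tips": len(tips),
                "tip_sample": ";".join(tips[:3]),
                "is_leaf": nd.is_leaf(),
                "states": "|".join(str(s) for s in states),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the whole analysis chain; returns paths of the written outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- load ------------------------------------------------------------
    try:
        matrix = io_formats.read_tnt_matrix(config.matrix_path)
        ages = io_formats.read_table(config.ages_path, "age")
        extant = io_formats.read_table(config.extant_path, "allometry")
        fossil_records = io_formats.read_table(config.fossil_path, "allometry")
        fossil_hw = {r.taxon: r.hw_cm for r in fossil_records}
        constraint = None
        if config.scaffold_path:
            constraint = parsimony.ScaffoldConstraint(
                backbone=io_formats.read_newick(Path(config.scaffold_path))
            )
    except Exception as exc:
        raise PipelineError("load", "parse_failure", str(exc)) from exc

    # --- search / consensus ----------------------------------------------
    try:
        if config.tree_path:
            consensus = io_formats.read_newick(Path(config.tree_path))
            logger.info("search skipped: using precomputed tree %s", config.tree_path)
        else:
            search_cfg = parsimony.SearchConfig(
                n_replicates=config.n_replicates,
                rearrangement=config.rearrangement,
                max_trees_retained=config.max_trees_retained,
                seed=config.seed,
                outgroup=config.outgroup,
            )
            trees = parsimony.heuristic_search(
                matrix, constraint=constraint, config=search_cfg
            )
            io_formats.write_newick_list(trees, out_dir / "mpts.nwk")
            outputs["mpts"] = out_dir / "mpts.nwk"
            consensus = parsimony.strict_consensus(trees)
        io_formats.write_newick(consensus, out_dir / "consensus.nwk", branch_lengths=False)
        outputs["consensus"] = out_dir / "consensus.nwk"
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("search", "search_failure", str(exc)) from exc

    # --- calibration ------------------------------------------------------
    try:
        cal_cfg = chronology.CalibrationConfig(
            min_branch=config.min_branch, tip_age_rule=config.tip_age_rule
        )
        time_tree = chronology.calibrate_mbl(consensus, ages, cal_cfg)
        io_formats.write_newick(time_tree, out_dir / "calibrated.nwk")
        outputs["calibrated"] = out_dir / "calibrated.nwk"
    except Exception as exc:
        raise PipelineError("calibrate", "calibration_failure", str(exc)) from exc

    # --- body-size prediction ---------------------------------------------
    try:
        mcmc = allometry.McmcConfig(
            n_iter=config.mcmc_iter,
            burn_in=config.mcmc_burn_in,
            thin=config.mcmc_thin,
            seed=config.seed,
        )
        model = allometry.fit_regression(extant, time_tree, mode="PGLS")
        predictions = allometry.predict_tl(
            time_tree, extant, fossil_hw, model_mode="PGLS", mcmc=mcmc, lam=model.lam
        )
        pred_df = allometry.predictions_to_frame(predictions)
        pred_df.to_csv(out_dir / "predictions.csv", index=False)
        outputs["predictions"] = out_dir / "predictions.csv"
    except Exception as exc:
        raise PipelineError("predict", "prediction_failure", str(exc)) from exc

    # --- binning + ancestral states ----------------------------------------
    try:
        mean_tl: dict[str, float] = {r.taxon: r.mean_cm for r in predictions}
        extant_means = allometry.taxon_log_means(extant, require_tl=True)
        for taxon, row in extant_means.iterrows():
            mean_tl[taxon] = 10 ** row["log_tl"]
        coarse = {t: size_evolution.size_bin_index(v) for t, v in mean_tl.items()}
        fine = {
            t: size_evolution.fine_bin_index(v, config.bin_width_cm)
            for t, v in mean_tl.items()
        }
        bin_df = pd.DataFrame(
            {
                "taxon": sorted(mean_tl),
                "mean_tl_cm": [mean_tl[t] for t in sorted(mean_tl)],
                "size_class": [
                    size_evolution.SIZE_BIN_NAMES[coarse[t]] for t in sorted(mean_tl)
                ],
                "fine_bin": [
                    size_evolution.fine_bin_label(fine[t], config.bin_width_cm)
                    for t in sorted(mean_tl)
                ],
            }
        )
        bin_df.to_csv(out_dir / "size_bins.csv", index=False)
        outputs["size_bins"] = out_dir / "size_bins.csv"

        asr = size_evolution.asr_bins(time_tree, fine)
        node_state_table(time_tree, asr).to_csv(out_dir / "asr_size.csv", index=False)
        outputs["asr_size"] = out_dir / "asr_size.csv"

        if config.osmo_path:
            osmo_df = pd.read_csv(config.osmo_path)
            states = dict(zip(osmo_df["taxon"].astype(str), osmo_df["state"].astype(str)))
            osmo_asr = size_evolution.asr_binary(time_tree, states)
            names = {0: "freshwater_only", 1: "saltwater_tolerant"}
            node_state_table(time_tree, osmo_asr, names).to_csv(
                out_dir / "asr_osmoregulation.csv", index=False
            )
            outputs["asr_osmoregulation"] = out_dir / "asr_osmoregulation.csv"
    except Exception as exc:
        raise PipelineError("asr", "asr_failure", str(exc)) from exc

    # --- manifest ----------------------------------------------------------
    manifest = {
        "package": {"paleocroc": __version__},
        "seed": config.seed,
        "config": asdict(config),
        "conventions": {
            "log_base": 10,
            "lambda_mode": "plug-in ML (held fixed during MCMC)",
            "tip_age_rule": config.tip_age_rule,
            "size_bin_upper_cm": [150, 400, 700, None],
            "fine_bin_width_cm": config.bin_width_cm,
        },
        "inputs": {
            name: _sha256(Path(p))
            for name, p in {
                "matrix": config.matrix_path,
                "ages": config.ages_path,
                "extant": config.extant_path,
                "fossil": config.fossil_path,
                "scaffold": config.scaffold_path,
                "tree": config.tree_path,
                "osmo": config.osmo_path,
            }.items()
            if p
        },
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
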