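"""Pipeline orchestration, the shipped folding-rate table, and summary
statistics of the locks-plus-neighbours cores."""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, survey
from .loops import find_loops_and_core
from .metrics import RateRecord, compute_metric, correlate_lnkf
from .structure import compute_contacts, compute_properties
from .synthetic import make_loop_protein, make_rate_table, save_dataset

logger = logging.getLogger("loopnlock")

__all__ = ["load_table2", "summarize_core_stats", "run_pipeline",
           "default_config", "synthetic_cohort"]


def load_table2() -> pd.DataFrame:
    """The shipped 43-protein folding-rate / core-size table.

    Columns: protein_id, residues, contacts, core_residues,
    core_contacts, ln_kf.
    """
    with resources.files("loopnlock.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def summarize_core_stats(records: pd.DataFrame) -> dict:
    """Summary of core sizes relative to whole proteins.

    Expects columns (protein_id, residues, contacts, core_residues,
    core_contacts, ln_kf).  Returns means of the core columns, the
    aggregate core/total percentages (ratios of sums), the mean +/- sd
    of the per-protein core-residue proportion, and the per-protein
    percentage table with its extremes.
    """
    required = {"protein_id", "residues", "contacts", "core_residues",
                "core_contacts", "ln_kf"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    df = records.copy()
    df["residue_pct"] = 100.0 * df.core_residues / df.residues
    df["contact_pct"] = 100.0 * df.core_contacts / df.contacts
    per_protein = df[["protein_id", "residue_pct", "contact_pct"]]
    return {
        "n_proteins": int(len(df)),
        "mean_core_contacts": float(df.core_contacts.mean()),
        "mean_core_residues": float(df.core_residues.mean()),
        "aggregate_contact_pct": float(100.0 * df.core_contacts.sum()
                                       / df.contacts.sum()),
        "aggregate_residue_pct": float(100.0 * df.core_residues.sum()
                                       / df.residues.sum()),
        "mean_residue_pct": float(df.residue_pct.mean()),
        "sd_residue_pct": float(df.residue_pct.std()),
        "min_residue_pct": float(df.residue_pct.min()),
        "min_residue_pct_protein": str(df.protein_id[df.residue_pct.idxmin()]),
        "max_residue_pct": float(df.residue_pct.max()),
        "max_residue_pct_protein": str(df.protein_id[df.residue_pct.idxmax()]),
        "per_protein": per_protein,
    }


# ---------------------------------------------------------------------------
# Synthetic end-to-end run
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Baseline configuration for a synthetic end-to-end run."""
    return {
        "seed": 0,
        "outdir": "loopnlock_run",
        "cohort": {"n_proteins": 12, "min_loops": 1, "max_loops": 2,
                   "lock_gap": 5.0},
        "rates": {"slope": -60.0, "intercept": 12.0, "noise_sd": 0.5,
                  "metric": "tcd", "source": "core"},
        "stages": {"loops": True, "metrics": True, "survey": True},
    }


def synthetic_cohort(n_proteins: int, seed, min_loops: int = 1,
                     max_loops: int = 2, lock_gap: float = 5.0):
    """A cohort of loop-planted bead proteins with varied lengths.

    Loop lengths are drawn from 15-40 residues; chain lengths follow
    from the planted loops plus flanking coil.  Returns
    ``(structures, manifests)``.
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    structures, manifests = [], []
    children = ss.spawn(n_proteins)
    for k in range(n_proteins):
        n_loops = int(rng.integers(min_loops, max_loops + 1))
        loops = []
        cursor = int(rng.integers(3, 12))
        for _ in range(n_loops):
            length = int(rng.integers(15, 41))
            loops.append((cursor, cursor + length - 1, lock_gap))
            cursor += length + int(rng.integers(4, 12))
        n_res = loops[-1][1] + int(rng.integers(5, 15))
        s, man = make_loop_protein(n_res, loops,
                                   seed=children[k].generate_state(1)[0] % (2 ** 31),
                                   protein_id=f"synth{k:03d}")
        structures.append(s)
        manifests.append(man)
    return structures, manifests


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def run_pipeline(config) -> dict:
    """Run the requested stages on a synthetic cohort.

    ``config`` is a dict or a path to a YAML file following
    :func:`default_config`.  Stages run in dependency order (cohort ->
    loops/cores -> metrics -> survey); every stage writes TSV/JSON
    artifacts into ``outdir`` and logs one line with its parameters and
    output digests.  Returns a report dict.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    base = default_config()
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            base[key].update(value)
        else:
            base[key] = value
    cfg = base
    stages = cfg["stages"]
    if stages.get("metrics") and not stages.get("loops"):
        raise ValueError("config error: the metrics stage requires the "
                         "loops stage (no cores without loops)")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "outdir": str(outdir)}

    structures, manifests = synthetic_cohort(
        cfg["cohort"]["n_proteins"], seed,
        cfg["cohort"]["min_loops"], cfg["cohort"]["max_loops"],
        cfg["cohort"]["lock_gap"])
    save_dataset(outdir / "structures", structures,
                 manifest={"cohort": manifests, "seed": seed})
    logger.info("stage=cohort n=%d seed=%d", len(structures), seed)

    cores, loop_rows = {}, []
    if stages.get("loops"):
        for s in structures:
            loops, core = find_loops_and_core(s)
            cores[s.id] = core
            for k, lp in enumerate(loops):
                loop_rows.append({
                    "protein_id": s.id, "loop_index": k, "start": lp.start,
                    "end": lp.end, "score": lp.score,
                    "lock_residues": ";".join(
                        map(str, (*lp.lock_a.residues, *lp.lock_b.residues))),
                    "minimal_pair": ";".join(map(str, lp.minimal_pair or ())),
                })
        loops_path = outdir / "loops.tsv"
        pd.DataFrame(loop_rows).to_csv(loops_path, sep="\t", index=False)
        cores_path = outdir / "cores.json"
        cores_path.write_text(json.dumps({
            pid: {"minimal_pairs": sorted(c.minimal_pair_residues),
                  "core_residues": sorted(c.core_residues),
                  "core_contacts": sorted(map(list, c.core_contacts))}
            for pid, c in cores.items() if c is not None}, indent=2))
        logger.info("stage=loops proteins=%d digest=%s,%s", len(cores),
                    _digest(loops_path), _digest(cores_path))
        report["n_loops"] = len(loop_rows)

    if stages.get("metrics"):
        rc = cfg["rates"]
        subsets = None
        if rc.get("source") == "core":
            subsets = {pid: set(c.core_contacts)
                       for pid, c in cores.items() if c is not None}
        usable = [s for s in structures
                  if subsets is None or subsets.get(s.id)]
        rates, rate_man = make_rate_table(
            usable, rc["slope"], rc["intercept"], rc["noise_sd"],
            rc["metric"], seed=seed + 1, contact_subsets=subsets)
        save_dataset(outdir, rates=rates)
        rows, all_vals, core_vals = [], {}, {}
        for s in usable:
            cmap = compute_contacts(s)
            all_vals[s.id] = compute_metric(cmap.pairs, s.length,
                                            rc["metric"])
            rows.append({"protein_id": s.id, "metric": rc["metric"],
                         "subset": "all", "value": all_vals[s.id],
                         "n_contacts": cmap.n_contacts})
            core = cores.get(s.id)
            if core is not None and core.core_contacts:
                core_vals[s.id] = compute_metric(core.core_contacts,
                                                 s.length, rc["metric"])
                rows.append({"protein_id": s.id, "metric": rc["metric"],
                             "subset": "core", "value": core_vals[s.id],
                             "n_contacts": len(core.core_contacts)})
        metrics_path = outdir / "metrics.tsv"
        pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False)
        corr = {"all": correlate_lnkf(all_vals, rates).__dict__}
        if len(core_vals) >= 3:
            corr["core"] = correlate_lnkf(core_vals, rates).__dict__
        corr_path = outdir / "correlations.json"
        corr_path.write_text(json.dumps(corr, indent=2))
        logger.info("stage=metrics metric=%s digest=%s,%s", rc["metric"],
                    _digest(metrics_path), _digest(corr_path))
        report["correlations"] = corr

    if stages.get("survey"):
        all_lengths, _ = survey.survey_cohort(structures)
        hist = survey.aggregate_distribution(all_lengths)
        hist["subset_tag"] = "all"
        survey_path = outdir / "loop_lengths.tsv"
        hist.to_csv(survey_path, sep="\t", index=False)
        logger.info("stage=survey digest=%s", _digest(survey_path))
        report["survey_modal_length"] = (
            int(hist.length[hist.density.idxmax()]) if len(hist) else None)

    (outdir / "run.json").write_text(json.dumps(
        {"config": {k: v for k, v in cfg.items()},
         "report": {k: v for k, v in report.items()
                    if k != "correlations"} | (
             {"correlations": report.get("correlations")}
             if "correlations" in report else {})},
        indent=2, default=str))
    return report
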