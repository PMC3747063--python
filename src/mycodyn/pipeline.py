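"""End-to-end pipeline orchestration.

Runs simulate (optional) -> absolute abundance -> rarefaction/richness ->
UniFrac/PCoA -> interval tests -> per-day distance tests, writing every
stage's table as TSV with a provenance header (seed, config hash,
versions).  Stage failures abort with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import (
    CorrectionParams,
    Group,
    abundance_table,
    group_summary,
)
from .community import aggregate_by_lineage, rarefy_table, rarefied_richness
from .io import (
    read_metadata,
    read_otu_table,
    read_qpcr,
    write_distance_matrix,
    write_metadata,
    write_newick,
    write_otu_table,
    write_qpcr,
)
from .phylodiversity import build_taxonomy_tree, pcoa, unifrac_matrix
from .stats import (
    IntervalScheme,
    default_scheme,
    distance_group_test,
    lineage_interval_tests,
)
from .synthetic import SimulationConfig, default_pool, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

GENUS_RANK = 5  # 0-based depth of the genus position in default lineages


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, parameters and output location for one pipeline run."""

    out_dir: str | Path = "mycodyn_out"
    seed: int = 0
    # either simulate=True, or provide the three input paths
    simulate: bool = True
    simulation: SimulationConfig | None = None
    metadata_path: str | Path | None = None
    qpcr_path: str | Path | None = None
    otu_16s_path: str | Path | None = None
    otu_its_path: str | Path | None = None
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    rarefaction_depth: int = 200
    rarefaction_reps: int = 10
    aggregation_rank: int = GENUS_RANK
    scheme: IntervalScheme | None = None
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # out_dir and log_level do not affect results; keep them out so the
        # hash identifies the computation, not where it was written
        skip = {"out_dir", "log_level"}

        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: enc(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if f.name not in skip
                }
            if isinstance(obj, (Path,)):
                return str(obj)
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple, set, frozenset)):
                return [enc(v) for v in obj]
            return obj

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict[str, object]:
    return {
        "mycodyn_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns a name -> path map of outputs."""
    logging.basicConfig(
        level=config.log_level, format="%(levelname)s %(name)s :: %(message)s"
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    outputs: dict[str, Path] = {}

    # ---- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            if sim.seed != config.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            pool = default_pool()
            records, measurements, t16, tits = simulate_experiment(sim, pool)
            write_metadata(records, out / "metadata.tsv", prov)
            write_qpcr(measurements, out / "qpcr.tsv", prov)
            write_otu_table(t16, out / "otu_16s.tsv", prov)
            write_otu_table(tits, out / "otu_its.tsv", prov)
            outputs.update(
                metadata=out / "metadata.tsv", qpcr=out / "qpcr.tsv",
                otu_16s=out / "otu_16s.tsv", otu_its=out / "otu_its.tsv",
            )
        else:
            for name, p in (
                ("metadata", config.metadata_path),
                ("qpcr", config.qpcr_path),
                ("otu_16s", config.otu_16s_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"missing {name} input: {p}")
            records = read_metadata(config.metadata_path)
            measurements = read_qpcr(config.qpcr_path)
            t16 = read_otu_table(config.otu_16s_path)
            tits = (
                read_otu_table(config.otu_its_path)
                if config.otu_its_path
                else None
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage: abundance --------------------------------------------------
    stage = "abundance"
    try:
        abund = abundance_table(records, measurements, config.correction)
        summary = group_summary(records, abund)
        _write_df(summary, out / "abundance_summary.tsv", prov)
        per_sample = pd.DataFrame(
            [dataclasses.asdict(a) for a in abund]
        )
        _write_df(per_sample, out / "abundance_per_sample.tsv", prov)
        outputs["abundance_summary"] = out / "abundance_summary.tsv"
        outputs["abundance_per_sample"] = out / "abundance_per_sample.tsv"
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    rng = np.random.default_rng(config.seed)
    tables = {"16s": t16}
    if tits is not None:
        tables["its"] = tits

    for label, table in tables.items():
        # ---- stage: richness ----------------------------------------------
        stage = f"richness[{label}]"
        try:
            rich = rarefied_richness(
                table, config.rarefaction_depth, config.rarefaction_reps, rng
            )
            df = pd.DataFrame([dataclasses.asdict(r) for r in rich])
            _write_df(df, out / f"richness_{label}.tsv", prov)
            outputs[f"richness_{label}"] = out / f"richness_{label}.tsv"
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage: diversity ---------------------------------------------
        stage = f"diversity[{label}]"
        try:
            rare = rarefy_table(table, config.rarefaction_depth, rng)
            tree = build_taxonomy_tree(
                {o: rare.lineages[o] for o in rare.otu_ids}
            )
            write_newick(tree, out / f"tree_{label}.nwk")
            dm_u = unifrac_matrix(tree, rare, weighted=False)
            dm_w = unifrac_matrix(tree, rare, weighted=True)
            write_distance_matrix(
                dm_u, out / f"unifrac_unweighted_{label}.tsv", prov
            )
            write_distance_matrix(
                dm_w, out / f"unifrac_weighted_{label}.tsv", prov
            )
            ord_u = pcoa(dm_u)
            coords = pd.DataFrame(
                ord_u.coordinates,
                index=ord_u.sample_ids,
                columns=[
                    f"PC{k + 1}" for k in range(ord_u.coordinates.shape[1])
                ],
            )
            coords.index.name = "sample_id"
            _write_df(
                coords.reset_index(), out / f"pcoa_{label}.tsv", prov
            )
            outputs[f"unifrac_unweighted_{label}"] = (
                out / f"unifrac_unweighted_{label}.tsv"
            )
            outputs[f"unifrac_weighted_{label}"] = (
                out / f"unifrac_weighted_{label}.tsv"
            )
            outputs[f"pcoa_{label}"] = out / f"pcoa_{label}.tsv"
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage: interval tests -----------------------------------------
        stage = f"interval_tests[{label}]"
        try:
            agg = aggregate_by_lineage(rare, config.aggregation_rank)
            observed_days = {
                r.day for r in records if r.sample_id in set(rare.sample_ids)
            }
            scheme = config.scheme or default_scheme().restrict_to_days(
                observed_days
            )
            results = lineage_interval_tests(agg, records, scheme)
            df = pd.DataFrame([dataclasses.asdict(r) for r in results])
            _write_df(df, out / f"interval_tests_{label}.tsv", prov)
            outputs[f"interval_tests_{label}"] = (
                out / f"interval_tests_{label}.tsv"
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

        # ---- stage: distance tests -----------------------------------------
        stage = f"distance_tests[{label}]"
        try:
            rows = []
            rare_ids = set(rare.sample_ids)
            kept = [r for r in records if r.sample_id in rare_ids]
            days = sorted({r.day for r in kept})
            for day in days:
                for grp in (Group.ABX_SHORT_TERM, Group.ABX_CONTINUOUS):
                    try:
                        p, direction = distance_group_test(
                            dm_w, kept, Group.CONTROL.value, grp.value, day
                        )
                    except ValueError:
                        continue
                    rows.append(
                        {
                            "day": day,
                            "treatment_group": grp.value,
                            "p": p,
                            "direction": direction,
                        }
                    )
            _write_df(
                pd.DataFrame(rows), out / f"distance_tests_{label}.tsv", prov
            )
            outputs[f"distance_tests_{label}"] = (
                out / f"distance_tests_{label}.tsv"
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc

    logger.info("pipeline complete: %d outputs in %s", len(outputs), out)
    return outputs


def _write_df(df: pd.DataFrame, path: Path, prov: dict[str, object]) -> None:
    with open(path, "w") as fh:
        for k, v in prov.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
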