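"""Config-driven end-to-end run: filter -> diversity -> clustering ->
ordination -> core microbiome -> endophyte screen, with a machine-readable
JSON run report.

The run config is a YAML/JSON mapping with stage toggles, per-stage
parameters (defaults: 1e-4 rare filter, 0.66/0.75 core thresholds,
alpha=0.001 with 5000 Monte-Carlo replicates for the endophyte screen,
999 permutations for ordination) and a mandatory seed for the stochastic
stages. Every parameter is echoed verbatim into the report, and identical
configs and inputs produce identical numerical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, community_data, diversity, endophytes, ordination
from . import core as core_mod
from .synthetic import StudyConfig, generate_study

__all__ = ["RunConfig", "run_pipeline", "simulate_to_dir"]

DEFAULT_STAGE_PARAMS = {
    "filter": {"min_fraction": 1e-4, "exclude_patterns": ["chloroplast"]},
    "diversity": {"group": "system", "test": "wilcoxon", "alpha": 0.05},
    "clustering": {"method": "spearman", "linkage": "average"},
    "ordination": {
        "variables": ["plant_label", "hydrology", "fraction", "pH", "ch4", "temperature"],
        "conditions": [],
        "n_perm": 999,
        "hellinger": False,
        "scheme": "marginal",
        "drop_aliased": True,
    },
    "core": {"total_threshold": 0.66, "species_threshold": 0.75},
    "endophytes": {
        "alpha": 0.001,
        "min_relabund": 0.005,
        "min_samples": 4,
        "n_rep": 5000,
    },
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    table_path: Path | None = None
    metadata_path: Path | None = None
    synthetic: StudyConfig | None = None
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            s: True for s in ("filter", "diversity", "clustering", "ordination", "core", "endophytes")
        }
    )
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages require one)")
        synth = None
        if "synthetic" in raw and raw["synthetic"] is not None:
            synth = StudyConfig(**raw["synthetic"])
        table_path = raw.get("table")
        metadata_path = raw.get("metadata")
        if synth is None and (table_path is None or metadata_path is None):
            raise ValueError("config needs either input paths or a synthetic block")
        stages = {s: True for s in DEFAULT_STAGE_PARAMS}
        stages.update(raw.get("stages", {}))
        unknown = set(stages) - set(DEFAULT_STAGE_PARAMS)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        params = {k: dict(v) for k, v in DEFAULT_STAGE_PARAMS.items()}
        for stage, p in raw.get("params", {}).items():
            if stage not in params:
                raise ValueError(f"unknown stage in params: {stage!r}")
            params[stage].update(p)
        return cls(
            seed=int(raw["seed"]),
            output_dir=base / raw.get("output_dir", "mossbiome_out"),
            table_path=base / table_path if table_path else None,
            metadata_path=base / metadata_path if metadata_path else None,
            synthetic=synth,
            stages=stages,
            params=params,
        )


def _pkg_version() -> str:
    try:
        return version("mossbiome")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    to ``<output_dir>/run_report.json``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": _pkg_version(),
        "seed": config.seed,
        "stages": dict(config.stages),
        "parameters": {k: _jsonable(v) for k, v in config.params.items()},
        "outputs": {},
        "wall_clock_s": {},
    }
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        s: int(rng.integers(2**31 - 1))
        for s in ("synthetic", "ordination", "endophytes")
    }

    if config.synthetic is not None:
        synth_cfg = config.synthetic
        if synth_cfg.seed == 0:
            synth_cfg = StudyConfig(**{**synth_cfg.to_dict(), "seed": stage_seeds["synthetic"]})
        table, metadata, truth = generate_study(synth_cfg)
        report["parameters"]["synthetic"] = _jsonable(synth_cfg.to_dict())
        community_data.write_otu_table(table, out / "otu_table.tsv")
        community_data.write_metadata(metadata, out / "metadata.tsv")
    else:
        table = community_data.read_otu_table(config.table_path)
        metadata = community_data.read_metadata(config.metadata_path)
    community_data.validate_metadata(table, metadata)

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        report["wall_clock_s"][stage] = round(time.perf_counter() - t0, 3)

    state = {"table": table}

    if config.stages.get("filter", True):
        def _filter():
            p = config.params["filter"]
            t = community_data.filter_taxa(state["table"], p["exclude_patterns"])
            t, rep = community_data.filter_rare(t, p["min_fraction"])
            state["table"] = t
            community_data.write_otu_table(t, out / "filtered_table.tsv")
            report["outputs"]["filter"] = {
                "entries_zeroed": rep.entries_zeroed,
                "otus_dropped": len(rep.otus_dropped),
                "n_otus": t.n_otus,
                "n_samples": t.n_samples,
            }
        timed("filter", _filter)

    tbl = state["table"]
    md = metadata.loc[list(tbl.sample_ids)]

    if config.stages.get("diversity", True):
        def _diversity():
            p = config.params["diversity"]
            df = diversity.diversity_frame(tbl)
            df.to_csv(out / "diversity.tsv", sep="\t")
            labels = md[p["group"]].to_numpy()
            test = (
                diversity.pairwise_wilcoxon
                if p["test"] == "wilcoxon"
                else diversity.pairwise_ttest
            )
            res = test(df["inverse_simpson"].to_numpy(), labels, alpha=p["alpha"])
            res.to_frame().to_csv(out / "diversity_pvalues.tsv", sep="\t")
            report["outputs"]["diversity"] = {
                "groups": list(res.groups),
                "letters": res.letters,
                "adjustment": res.adjustment,
            }
        timed("diversity", _diversity)

    if config.stages.get("clustering", True):
        def _clustering():
            p = config.params["clustering"]
            rel = community_data.relative_abundance(tbl)
            cor = clustering.correlation_matrix(
                rel.values, method=p["method"], sample_ids=list(tbl.sample_ids)
            )
            dend = clustering.agnes(
                clustering.cor_to_dissimilarity(cor),
                linkage=p["linkage"],
                leaf_labels=list(tbl.sample_ids),
            )
            (out / "dendrogram.nwk").write_text(clustering.export_newick(dend) + "\n")
            pd.DataFrame(cor, index=list(tbl.sample_ids), columns=list(tbl.sample_ids)).to_csv(
                out / "correlation.tsv", sep="\t"
            )
            report["outputs"]["clustering"] = {
                "agglomerative_coefficient": dend.agglomerative_coefficient,
                "linkage": dend.linkage,
                "dissimilarity": "1 - r",
            }
        timed("clustering", _clustering)

    if config.stages.get("ordination", True):
        def _ordination():
            p = config.params["ordination"]
            variables = [v for v in p["variables"] if v in md.columns]
            cm = ordination.prepare_constraints(md, variables + list(p["conditions"]))
            if p["hellinger"]:
                from types import SimpleNamespace

                data = SimpleNamespace(
                    values=community_data.hellinger(tbl),
                    sample_ids=tbl.sample_ids,
                    otu_ids=tbl.otu_ids,
                )
            else:
                data = tbl
            usable = [v for v in variables if cm.variable_columns.get(v)]
            usable_conds = [c for c in p["conditions"] if cm.variable_columns.get(c)]
            fit = ordination.cca(
                data,
                cm.subset(usable),
                cm.subset(usable_conds) if usable_conds else None,
                drop_aliased=p["drop_aliased"],
            )
            vp = ordination.variance_partition(
                data,
                cm,
                variables=usable,
                scope_conditions=usable_conds,
                n_perm=p["n_perm"],
                seed=stage_seeds["ordination"],
                scheme=p["scheme"],
                drop_aliased=p["drop_aliased"],
            )
            fit.site_scores.to_csv(out / "cca_site_scores.tsv", sep="\t")
            fit.species_scores.to_csv(out / "cca_species_scores.tsv", sep="\t")
            vp.table.to_csv(out / "variance_partition.tsv", sep="\t", index=False)
            report["outputs"]["ordination"] = {
                "total_inertia": fit.total_inertia,
                "constrained_inertia": fit.constrained_inertia,
                "constrained_pct": 100 * fit.constrained_inertia / fit.total_inertia,
                "dropped_variables": cm.dropped_variables,
                "partition": vp.table.to_dict(orient="records"),
            }
        timed("ordination", _ordination)

    if config.stages.get("core", True):
        def _core():
            p = config.params["core"]
            results = []
            results += core_mod.core_profiles("total", tbl, md, p["total_threshold"], p["species_threshold"])
            results += core_mod.core_profiles("per_system", tbl, md, p["total_threshold"], p["species_threshold"])
            results += core_mod.core_profiles("per_species", tbl, md, p["total_threshold"], p["species_threshold"])
            rows = []
            for r in results:
                rows.append(
                    dict(
                        name=r.name,
                        threshold=r.threshold,
                        min_count=r.min_count,
                        n_scope=r.n_scope_samples,
                        n_core=len(r),
                        contribution={g: list(v) for g, v in r.contribution.items()},
                    )
                )
                (out / f"core_{r.name}.txt").write_text("\n".join(r.core_otu_ids) + "\n")
            report["outputs"]["core"] = rows
            state["cores"] = results
        timed("core", _core)

    if config.stages.get("endophytes", True):
        def _endophytes():
            p = config.params["endophytes"]
            calls = endophytes.classify_endophytes(
                tbl,
                md,
                alpha=p["alpha"],
                min_relabund=p["min_relabund"],
                min_samples=p["min_samples"],
                n_rep=p["n_rep"],
                seed=stage_seeds["endophytes"],
            )
            qual = [c for c in calls if c.qualifies]
            rows = [
                dict(
                    otu_id=c.otu_id,
                    n_significant=c.n_significant_endo_higher,
                    n_above_abundance=c.n_samples_above_abundance,
                    qualifies=c.qualifies,
                )
                for c in calls
            ]
            pd.DataFrame(rows).to_csv(out / "endophyte_calls.tsv", sep="\t", index=False)
            if qual:
                hm = endophytes.heatmap_matrix(calls)
                hm["matrix"].to_csv(out / "endophyte_heatmap.tsv", sep="\t")
            report["outputs"]["endophytes"] = {
                "n_tested": len(calls),
                "n_qualifying": len(qual),
                "qualifying": [c.otu_id for c in qual],
            }
        timed("endophytes", _endophytes)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def simulate_to_dir(study: StudyConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic study and write table, metadata and truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, metadata, truth = generate_study(study)
    community_data.write_otu_table(table, out / "otu_table.tsv")
    community_data.write_metadata(metadata, out / "metadata.tsv")
    truth_rows = (
        [{"otu_id": o, "role": "core"} for o in truth.planted_core_ids]
        + [
            {"otu_id": o, "role": f"specific_{sys}"}
            for sys, ids in truth.planted_system_specific_ids.items()
            for o in ids
        ]
        + [{"otu_id": o, "role": "endophyte"} for o in truth.planted_endophyte_ids]
    )
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    return {
        "n_otus": table.n_otus,
        "n_samples": table.n_samples,
        "out_dir": str(out),
    }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
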