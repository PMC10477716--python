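"""End-to-end orchestration: simulate or load data, run every stage, and
emit a reproducible report.

Stage order follows the data dependencies: mineralization -> EEM correction
/ indices / PARAFAC -> community ordination -> co-occurrence networks
(global, per-treatment, modules, eigengene-environment associations) ->
driver attribution (random forest + variance partitioning). A single global
seed deterministically derives per-stage seeds, so a rerun with the same
config produces a bit-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as cm
from . import drivers as dr
from . import eem as ee
from . import mineralization as mz
from . import network as nw
from . import parafac as pf
from . import synth
from ._utils import derive_seed
from . import __version__

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of real inputs or a simulate block."""

    seed: int
    output_dir: str
    simulate: dict | None = None  # SynthDesign kwargs (minus seed)
    inputs: dict | None = None  # paths: eem_dir, blank, otu_*, metadata, titration
    parafac: dict = field(
        default_factory=lambda: {"n_components": 3, "n_starts": 10, "tol": 1e-8, "max_iter": 2500}
    )
    network: dict = field(
        default_factory=lambda: {"alpha": 0.01, "min_prevalence": 0.5, "resolution": 1.0}
    )
    drivers: dict = field(default_factory=lambda: {"n_trees": 500, "n_permutations": 49})
    associations: dict = field(default_factory=lambda: {"n_permutations": 999})

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")
        if self.seed is None:
            raise ValueError("a global seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls(seed=doc["seed"], output_dir=doc.get("output_dir", "soilcnet_out"),
                   simulate=doc.get("simulate"), inputs=doc.get("inputs"))
        for key in ("parafac", "network", "drivers", "associations"):
            if key in doc:
                getattr(base, key).update(doc[key])
        return base

    def canonical(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so report serialization is stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: dict
    warnings: list

    def to_json(self, path) -> None:
        payload = _round_floats(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "stages": self.stages,
                "warnings": self.warnings,
            }
        )
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    def report_hash(self) -> str:
        payload = _round_floats({"stages": self.stages, "warnings": self.warnings})
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    def to_text(self, path) -> None:
        lines = [f"soilcnet {self.version} run report (config {self.config_hash})", ""]
        for stage, summary in sorted(self.stages.items()):
            lines.append(f"[{stage}]")
            lines.append(json.dumps(_round_floats(summary), indent=2, sort_keys=True))
            lines.append("")
        if self.warnings:
            lines.append("warnings:")
            lines += [f"  - {w}" for w in self.warnings]
        Path(path).write_text("\n".join(lines))


def _simulate(config: PipelineConfig, out: Path, report: dict, warnings_list: list):
    sim = dict(config.simulate or {})
    fungi_kwargs = sim.pop("fungi", {})
    mineral_kwargs = sim.pop("mineralization", {})
    design = synth.SynthDesign(seed=derive_seed(config.seed, "simulate"), **sim)

    cube, blank, eem_truth = synth.gen_eem_dataset(design)
    bact_table, bact_truth = synth.gen_community(design)
    fungi_defaults = {"n_taxa": 120, "n_modules": 3, "module_size": 20}
    fungi_defaults.update(fungi_kwargs)
    fungi_design = synth.SynthDesign(
        seed=derive_seed(config.seed, "simulate-fungi"),
        **{**{k: v for k, v in sim.items() if k not in fungi_defaults}, **fungi_defaults},
    )
    fungi_table, fungi_truth = synth.gen_community(fungi_design)
    titr, titr_truth = synth.gen_mineralization(
        synth.SynthDesign(seed=derive_seed(config.seed, "simulate-mineral"),
                          **{k: v for k, v in sim.items()}),
        **mineral_kwargs,
    )

    sim_dir = out / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    cube.to_dir(sim_dir / "eems")
    blank.to_dir(sim_dir / "blank")
    bact_table.to_tsv(sim_dir / "otu_bacteria.tsv", sim_dir / "metadata.tsv")
    fungi_table.to_tsv(sim_dir / "otu_fungi.tsv", sim_dir / "metadata_fungi.tsv")
    titr.to_tsv(sim_dir / "titration.tsv")
    eem_truth.to_json(sim_dir / "truth_eem.json")
    bact_truth.to_json(sim_dir / "truth_bacteria.json")
    fungi_truth.to_json(sim_dir / "truth_fungi.json")
    titr_truth.to_json(sim_dir / "truth_mineralization.json")

    report["simulate"] = {
        "n_samples": design.n_samples,
        "treatments": list(design.treatments),
        "n_taxa_bacteria": bact_table.counts.shape[0],
        "n_taxa_fungi": fungi_table.counts.shape[0],
    }
    return cube, blank, bact_table, fungi_table, titr


def _load_inputs(config: PipelineConfig):
    paths = config.inputs
    cube = ee.EEMCube.from_dir(paths["eem_dir"])
    blank = ee.EEMCube.from_dir(paths["blank_dir"])
    bact = cm.OTUTable.from_tsv(paths["otu_bacteria"], paths["metadata"])
    fungi = cm.OTUTable.from_tsv(paths["otu_fungi"], paths["metadata"])
    titr = mz.TitrationTable.from_tsv(paths["titration"])
    return cube, blank, bact, fungi, titr


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order and write every artifact.

    Returns the :class:`RunReport`; also writes ``report.json`` and
    ``report.txt`` plus per-stage output files under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    warns: list[str] = []

    try:
        if config.simulate is not None:
            cube, blank, bact_table, fungi_table, titr = _simulate(config, out, stages, warns)
        else:
            cube, blank, bact_table, fungi_table, titr = _load_inputs(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # ------------------------------------------------------ mineralization
    try:
        series = mz.cumulative_mineralization(titr)
        cum = series.cum_final()
        series.per_jar.to_csv(out / "mineralization_series.tsv", sep="\t", index=False)
        summary = series.treatment_summary()
        summary.to_json(out / "mineralization_summary.json", indent=2)
        stages["mineralization"] = {
            "cum_mean_by_treatment": summary["mean"].round(2).to_dict(),
            "cum_se_by_treatment": summary["se"].round(3).to_dict(),
            "clipped_intervals": series.clipped_intervals,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'mineralization' failed: {exc}") from exc

    # ------------------------------------------------------------- eem
    try:
        corrected = ee.correct_eems(cube, blank)
        indices = ee.compute_indices(corrected)
        indices.to_csv(out / "fluorescence_indices.tsv", sep="\t")
        stages["eem"] = {
            "raman_area": corrected.provenance["raman_area"],
            "excised_cells": corrected.provenance["excised_cells"],
            "clipped_cells": corrected.provenance["clipped_cells"],
            "BIX_mean": float(np.nanmean(indices["BIX"])),
            "HIX_mean": float(np.nanmean(indices["HIX"])),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'eem' failed: {exc}") from exc

    # ---------------------------------------------------------- parafac
    try:
        pcfg = config.parafac
        model = pf.fit_parafac(
            corrected,
            n_components=pcfg.get("n_components", 3),
            n_starts=pcfg.get("n_starts", 10),
            tol=pcfg.get("tol", 1e-8),
            max_iter=pcfg.get("max_iter", 2500),
            seed=derive_seed(config.seed, "parafac"),
        )
        model.to_dir(out / "parafac")
        fmax = pf.compute_fmax(model)
        fmax.rename_axis("sample").to_csv(out / "parafac" / "fmax.csv")
        rel = pf.fmax_relative(fmax)
        matches = pf.match_components(model, pf.default_library())
        stages["parafac"] = {
            "explained_variance": model.explained_variance,
            "em_peaks": model.em_peaks().tolist(),
            "ex_peaks": model.ex_peaks().tolist(),
            "converged": model.convergence["converged"],
            "degenerate": model.degenerate,
            "library_matches": {
                m.component: {"label": m.label, "tcc_ex": m.tcc_ex, "tcc_em": m.tcc_em, "matched": m.matched}
                for m in matches
            },
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'parafac' failed: {exc}") from exc

    # -------------------------------------------------------- community
    try:
        stages["community"] = {}
        distances = {}
        for name, table in (("bacteria", bact_table), ("fungi", fungi_table)):
            rel_ab = cm.relative_abundance(table, rank="class")
            rel_ab.to_csv(out / f"relative_abundance_{name}.tsv", sep="\t")
            dmat = cm.bray_curtis(table)
            dmat.to_tsv(out / f"bray_curtis_{name}.tsv")
            distances[name] = dmat
            ord_res = cm.pcoa(dmat)
            ord_res.coordinates.to_csv(out / f"pcoa_{name}.tsv", sep="\t")
            ad = cm.permanova(
                dmat,
                table.metadata.loc[dmat.sample_ids, "treatment"],
                n_permutations=999,
                seed=derive_seed(config.seed, f"permanova-{name}"),
            )
            stages["community"][name] = {
                "adonis_r2": ad.r_squared,
                "adonis_p": ad.p_value,
                "pcoa_axis1_fraction": float(ord_res.fractions[0]) if len(ord_res.fractions) else None,
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'community' failed: {exc}") from exc

    # ---------------------------------------------------------- network
    try:
        ncfg = config.network
        stages["network"] = {}
        acc_by_treatment: dict[str, dict[str, float]] = {}
        eigengenes = {}
        for name, table in (("bacteria", bact_table), ("fungi", fungi_table)):
            filt = nw.prevalence_filter(table, min_fraction=ncfg.get("min_prevalence", 0.5))
            net = nw.correlation_network(filt, alpha=ncfg.get("alpha", 0.01))
            modules, q = nw.detect_modules(
                net,
                seed=derive_seed(config.seed, f"louvain-{name}"),
                resolution=ncfg.get("resolution", 1.0),
            )
            net.to_graphml(out / f"network_{name}.graphml")
            net.edge_table().to_csv(out / f"edges_{name}.csv", index=False)
            topo = nw.topology(net)
            treatment_topo = {}
            accs = {}
            for t in sorted(set(table.metadata["treatment"])):
                sub = nw.treatment_subnetwork(net, table, t, min_fraction=ncfg.get("min_prevalence", 0.5))
                tm = nw.topology(sub)
                treatment_topo[t] = tm.as_dict()
                accs[t] = tm.average_clustering_coefficient
            acc_by_treatment[name] = accs
            # Module eigengenes for modules with >= 3 members.
            megs = []
            for mid in sorted(set(modules.values())):
                members = [n for n, m in modules.items() if m == mid]
                if len(members) >= 3:
                    megs.append(nw.module_eigengene(table.counts, members, module_id=mid))
            eg_frame = pd.DataFrame({f"{name}_ME{m.module_id}": m.values for m in megs})
            eigengenes[name] = eg_frame
            pd.DataFrame(treatment_topo).to_json(out / f"topology_{name}.json", indent=2)
            stages["network"][name] = {
                "global": topo.as_dict(),
                "by_treatment": treatment_topo,
                "modularity": q,
                "n_modules": len(set(modules.values())),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # ------------------------------------------- eigengene associations
    try:
        indices_num = indices[["BIX", "HIX", "FI"]]
        env = pd.concat([indices_num, fmax, rel.add_suffix("_rel")], axis=1)
        env["cum"] = cum.reindex(env.index)
        acfg = config.associations
        assoc_frames = []
        for name, eg in eigengenes.items():
            if eg.empty:
                continue
            assoc = nw.module_env_association(
                eg,
                env,
                n_permutations=acfg.get("n_permutations", 999),
                seed=derive_seed(config.seed, f"assoc-{name}"),
            )
            assoc.insert(0, "community", name)
            assoc_frames.append(assoc)
        if assoc_frames:
            assoc_all = pd.concat(assoc_frames, ignore_index=True)
            assoc_all.to_csv(out / "module_env_associations.tsv", sep="\t", index=False)
            stages["associations"] = {
                "n_tests": int(len(assoc_all)),
                "n_significant_p05": int((assoc_all["p_perm"] < 0.05).sum()),
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'associations' failed: {exc}") from exc

    # ---------------------------------------------------------- drivers
    try:
        dcfg = config.drivers
        doc_block = pd.concat([fmax.add_prefix("Fmax_"), rel["C1"].rename("C1_rel"), indices_num], axis=1)
        treatments = bact_table.metadata.loc[doc_block.index, "treatment"]
        bacc = treatments.map(acc_by_treatment["bacteria"]).rename("BACC")
        facc = treatments.map(acc_by_treatment["fungi"]).rename("FACC")
        warns.append(
            "BACC/FACC are treatment-level network metrics broadcast to replicate "
            "samples (pseudo-replication in the driver table)"
        )
        driver_table = pd.concat([doc_block, bacc, facc], axis=1)
        driver_table["cum"] = cum.reindex(driver_table.index)
        driver_table = driver_table.dropna()
        driver_table.rename_axis("sample").to_csv(out / "driver_table.tsv", sep="\t")

        rf = dr.rf_importance(
            driver_table,
            response="cum",
            n_trees=dcfg.get("n_trees", 500),
            n_permutations=dcfg.get("n_permutations", 49),
            seed=derive_seed(config.seed, "rf"),
        )
        rf.importance.to_csv(out / "rf_importance.tsv", sep="\t")
        x1_cols = list(doc_block.columns)
        x2_cols = ["BACC", "FACC"]
        vpa = dr.variance_partition(
            driver_table["cum"], driver_table[x1_cols], driver_table[x2_cols]
        )
        try:
            shares = dr.within_category_share(driver_table["cum"], driver_table[x2_cols])
            share_summary = shares["share_standalone_pct"].round(2).to_dict()
        except ValueError as exc:
            warns.append(f"within-category shares undefined: {exc}")
            share_summary = {}
        (out / "vpa.json").write_text(
            json.dumps(_round_floats({
                "fractions": vpa.fractions(),
                "r2": {"x1": vpa.r2_x1, "x2": vpa.r2_x2, "both": vpa.r2_both},
                "suppression": vpa.suppression,
                "x1_columns": x1_cols,
                "x2_columns": x2_cols,
            }), indent=2, sort_keys=True)
        )
        stages["drivers"] = {
            "rf_top_predictors": rf.importance.index[:3].tolist(),
            "rf_model_p": rf.model_p,
            "rf_oob_r2": rf.oob_r2,
            "rf_importance_pct": rf.importance["inc_mse_pct"].round(3).to_dict(),
            "rf_p_perm": rf.importance["p_perm"].round(4).to_dict(),
            "vpa": vpa.fractions(),
            "network_within_share_pct": share_summary,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'drivers' failed: {exc}") from exc

    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
        warnings=warns,
    )
    report.to_json(out / "report.json")
    report.to_text(out / "report.txt")
    return report
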