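"""End-to-end orchestration: simulate -> quantify -> normalize -> rollup ->
differential -> network -> enrichment, with a manifest and stage caching.

Each stage reads its inputs from the run directory, writes CSV/JSON
outputs and records input/output SHA-256 checksums plus parameters and
wall time in ``manifest.json``. A rerun skips stages whose recorded input
checksums and outputs are unchanged; a corrupted intermediate raises an
integrity error naming the file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance, differential, enrichment, network, normalize, quant, simulate
from .errors import ConfigurationError, IntegrityError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "normalize", "rollup", "diff", "network", "enrich")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    seed: int = 17
    simulation: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    n_macro_clusters: int = 6
    stages: tuple = STAGES
    log_level: str = "INFO"

    def sim_config(self) -> simulate.SimulationConfig:
        d = dict(self.simulation)
        d.setdefault("seed", self.seed)
        return simulate.config_from_dict(d)

    def net_config(self) -> network.NetworkConfig:
        return network.NetworkConfig(**self.network)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown run options: {sorted(unknown)}")
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Stateful runner over a run directory with manifest bookkeeping."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.dir = Path(config.out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text()) if self.manifest_path.exists() else {}
        )

    # -- manifest helpers ----------------------------------------------
    def _save_manifest(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))

    def _params(self, stage: str) -> str:
        cfg = dataclasses.asdict(self.config)
        cfg.pop("out_dir", None)
        return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()

    def _verify_inputs(self, stage: str, inputs: list) -> dict:
        """Check inputs exist and match the checksum their producer recorded."""
        hashes = {}
        produced = {}
        for st, entry in self.manifest.items():
            for f, h in entry.get("outputs", {}).items():
                produced[f] = h
        for name in inputs:
            path = self.dir / name
            if not path.exists():
                raise ConfigurationError(f"stage {stage}: missing input {path}")
            h = _sha256(path)
            if name in produced and produced[name] != h:
                raise IntegrityError(
                    f"stage {stage}: input file {path} does not match the "
                    f"checksum recorded by its producing stage"
                )
            hashes[name] = h
        return hashes

    def _fresh(self, stage: str, inputs: dict) -> bool:
        entry = self.manifest.get(stage)
        if not entry or entry.get("status") != "ok":
            return False
        if entry.get("params") != self._params(stage):
            return False
        if entry.get("inputs") != inputs:
            return False
        for f, h in entry.get("outputs", {}).items():
            path = self.dir / f
            if not path.exists() or _sha256(path) != h:
                return False
        return True

    def _run_stage(self, stage: str, inputs: list, fn) -> None:
        try:
            in_hashes = self._verify_inputs(stage, inputs)
        except Exception:
            self.manifest[stage] = {"status": "failed", "params": self._params(stage)}
            self._save_manifest()
            raise
        if self._fresh(stage, in_hashes):
            logger.info("stage %s: up to date, skipped", stage)
            self.manifest[stage]["skipped"] = True
            self._save_manifest()
            return
        t0 = time.monotonic()
        try:
            outputs = fn()
        except Exception:
            self.manifest[stage] = {"status": "failed", "inputs": in_hashes,
                                    "params": self._params(stage)}
            self._save_manifest()
            raise
        self.manifest[stage] = {
            "status": "ok",
            "skipped": False,
            "inputs": in_hashes,
            "params": self._params(stage),
            "outputs": {f: _sha256(self.dir / f) for f in outputs},
            "wall_time_s": round(time.monotonic() - t0, 3),
        }
        self._save_manifest()

    # -- stages --------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config.sim_config()

        def fn():
            cohort = simulate.generate_cohort(cfg)
            targets = simulate.generate_target_list(cfg)
            table, ref_areas, truth = simulate.generate_transitions(cohort, targets, cfg)
            cohort.to_csv(self.dir / "cohort.csv", index=False)
            targets.to_csv(self.dir / "targets.csv", index=False)
            quant.write_transition_report(table, self.dir / "transitions.csv")
            simulate.write_truth_json(truth, self.dir / "truth.json")
            sets = simulate.generate_annotation_sets(cfg)
            with open(self.dir / "gene_sets.tsv", "w") as fh:
                for term, genes in sets.items():
                    for g in genes:
                        fh.write(f"{term}\t{g}\n")
            return ["cohort.csv", "targets.csv", "transitions.csv", "truth.json",
                    "gene_sets.tsv"]

        self._run_stage("simulate", [], fn)

    def stage_quantify(self) -> None:
        def fn():
            table = quant.read_transition_report(self.dir / "transitions.csv")
            peptides = quant.quantify_peptides(table)
            peptides.values.to_csv(self.dir / "peptide_matrix.csv")
            meta = {"sample_injections": peptides.sample_injections,
                    "entity_map": peptides.entity_map}
            (self.dir / "peptide_meta.json").write_text(json.dumps(meta, indent=1))
            return ["peptide_matrix.csv", "peptide_meta.json"]

        self._run_stage("quantify", ["transitions.csv"], fn)

    def _load_peptides(self) -> abundance.AbundanceMatrix:
        values = pd.read_csv(self.dir / "peptide_matrix.csv", index_col=0)
        meta = json.loads((self.dir / "peptide_meta.json").read_text())
        return abundance.AbundanceMatrix(
            values=values, level="peptide",
            sample_injections=meta["sample_injections"],
            entity_map=meta["entity_map"],
        )

    def stage_normalize(self) -> None:
        def fn():
            peptides = self._load_peptides()
            targets = pd.read_csv(self.dir / "targets.csv")
            panel = normalize.build_reference_panel(peptides, targets)
            normalize.select_reference_peptides(panel)
            cf = normalize.compute_correction_factors(panel)
            corrected = normalize.apply_correction(peptides, cf)
            corrected.values.to_csv(self.dir / "peptide_corrected.csv")
            qc = normalize.qc_report(panel)
            (self.dir / "normalization_qc.json").write_text(json.dumps(qc, indent=1))
            return ["peptide_corrected.csv", "normalization_qc.json"]

        self._run_stage(
            "normalize", ["peptide_matrix.csv", "peptide_meta.json", "targets.csv"], fn
        )

    def stage_rollup(self) -> None:
        def fn():
            peptides = self._load_peptides()
            corrected = peptides.advance(
                "corrected",
                values=pd.read_csv(self.dir / "peptide_corrected.csv", index_col=0),
            )
            targets = pd.read_csv(self.dir / "targets.csv")
            cohort = pd.read_csv(self.dir / "cohort.csv")
            protein = abundance.rollup_proteins(corrected, targets)
            # pooled-standard injections are excluded from group statistics
            cases = [c for c in protein.values.columns if not c.startswith("GPS")]
            protein = dataclasses.replace(protein, values=protein.values[cases])
            protein, report = abundance.impute_half_min(protein)
            protein = abundance.log2_transform(protein)
            protein, coefs = abundance.residualize_covariates(protein, cohort)
            protein.values.to_csv(self.dir / "protein_matrix.csv")
            coefs.to_csv(self.dir / "covariate_coefficients.csv")
            (self.dir / "imputation_report.json").write_text(
                json.dumps({k: v for k, v in report.items()}, indent=1)
            )
            return ["protein_matrix.csv", "covariate_coefficients.csv",
                    "imputation_report.json"]

        self._run_stage(
            "rollup",
            ["peptide_corrected.csv", "peptide_meta.json", "targets.csv", "cohort.csv"],
            fn,
        )

    def _load_protein(self) -> abundance.AbundanceMatrix:
        values = pd.read_csv(self.dir / "protein_matrix.csv", index_col=0)
        return abundance.AbundanceMatrix(
            values=values, level="protein",
            stages=("corrected", "imputed", "log2", "residualized"),
        )

    def stage_diff(self) -> None:
        def fn():
            protein = self._load_protein()
            cohort = pd.read_csv(self.dir / "cohort.csv")
            volcano = differential.volcano_all(protein, cohort)
            volcano.to_csv(self.dir / "volcano.csv", index=False)
            omnibus = differential.omnibus_tests(protein, cohort)
            omnibus.to_csv(self.dir / "omnibus.csv", index=False)
            return ["volcano.csv", "omnibus.csv"]

        self._run_stage("diff", ["protein_matrix.csv", "cohort.csv"], fn)

    def stage_network(self) -> None:
        def fn():
            protein = self._load_protein()
            cohort = pd.read_csv(self.dir / "cohort.csv")
            cfg = self.config.net_config()
            partition = network.build_network(protein.values, cfg)
            pd.DataFrame(
                {
                    "entity": list(partition.assignment),
                    "module": [partition.assignment[e] for e in partition.assignment],
                }
            ).to_csv(self.dir / "modules.csv", index=False)
            partition.eigenproteins.to_csv(self.dir / "eigenproteins.csv")
            partition.kme.to_csv(self.dir / "kme.csv")
            traits = network.module_trait_correlations(partition, cohort)
            traits.to_csv(self.dir / "module_traits.csv", index=False)
            ranking = network.pathology_ranking(protein.values)
            ranking.to_csv(self.dir / "pathology_ranking.csv", index=False)
            return ["modules.csv", "eigenproteins.csv", "kme.csv",
                    "module_traits.csv", "pathology_ranking.csv"]

        self._run_stage("network", ["protein_matrix.csv", "cohort.csv"], fn)

    def stage_enrich(self) -> None:
        def fn():
            modules = pd.read_csv(self.dir / "modules.csv")
            protein = self._load_protein()
            sets = enrichment.read_gene_sets(self.dir / "gene_sets.tsv")
            background = list(protein.values.index)
            module_genes = {
                m: list(sub["entity"])
                for m, sub in modules.groupby("module")
                if m != "M0"
            }
            table = enrichment.enrichment_table(module_genes, sets, background)
            table.to_csv(self.dir / "enrichment.csv", index=False)
            zmat = enrichment.z_matrix(table)
            labels, row_order, col_order = enrichment.cocluster_z_matrix(
                zmat, self.config.n_macro_clusters
            )
            labels.to_frame().to_csv(self.dir / "macro_clusters.csv")
            return ["enrichment.csv", "macro_clusters.csv"]

        self._run_stage("enrich", ["modules.csv", "protein_matrix.csv", "gene_sets.tsv"], fn)

    # -- driver --------------------------------------------------------
    def run(self) -> dict:
        """Execute the configured stages in order; returns the manifest."""
        fns = {
            "simulate": self.stage_simulate,
            "quantify": self.stage_quantify,
            "normalize": self.stage_normalize,
            "rollup": self.stage_rollup,
            "diff": self.stage_diff,
            "network": self.stage_network,
            "enrich": self.stage_enrich,
        }
        for stage in STAGES:
            if stage in self.stages_requested:
                fns[stage]()
        (self.dir / "run_config.json").write_text(
            json.dumps(dataclasses.asdict(self.config), indent=1, default=str)
        )
        return self.manifest

    @property
    def stages_requested(self) -> tuple:
        return tuple(self.config.stages)


def run(config: RunConfig) -> dict:
    """Run the full pipeline; returns the manifest dictionary."""
    return PipelineRun(config).run()
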