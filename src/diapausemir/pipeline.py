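"""End-to-end orchestration of the synthetic study from one YAML config.

``run_all`` executes: synthetic catalog and metadata -> per-sample
small-RNA FASTQ with planted abundances -> quantification -> NB
differential expression for every comparison that resolves in the
metadata -> arm-switch detection -> convergence analyses (signed DEM
overlap, PCA, per-species activity summary) -> per-miRNA target
enrichment on a synthetic target map -> genomic-read simulation and
miR-430-style copy-number comparison. Every stage writes its outputs
under the configured directory and records a sha256 in the run
manifest; identical config and seed give identical manifests.

The global seed fans out to per-stage seeds through a fixed counter so
stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import armswitch, convergence, copynumber, diffexpr, io, quant, simulate
from .core import (
    ComparisonDesign,
    SampleMeta,
    ValidationError,
    standard_designs,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Knobs of the demo study; defaults are desk-scale."""

    out_dir: str = "run_out"
    seed: int = 1
    # catalog / counts
    n_loci: int = 20
    baseline_log2_mean: float = 4.5
    baseline_log2_sd: float = 1.0
    planted_dem_fraction: float = 0.15
    planted_lfc: float = 2.0
    planted_switch_loci: int = 2
    # thresholds
    alpha: float = 0.05
    activity: float = 10.0
    max_mismatches: int = 2
    max_edits: int = 2
    # copy-number stage
    genome_length: int = 60_000
    read_length: int = 100
    coverage: float = 2.0
    copies_annual: int = 6
    copies_nonannual: int = 18
    n_species_per_group: int = 3
    # enrichment stage
    n_genes: int = 300
    n_degs: int = 60
    targets_per_mirna: int = 12

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.alpha <= 0 or cfg.activity <= 0:
            raise ValidationError("thresholds must be positive")
        return cfg


def _stage_seed(seed: int, stage_index: int) -> int:
    """Derive a per-stage seed from the global one (kept below 2**31)."""
    return int((seed * 1_000_003 + stage_index * 7919) % (2**31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _study_metadata(n_skip: int = 3) -> list[SampleMeta]:
    """Metadata mirroring the study design: 8 annual-diapause and 7
    non-annual libraries across three clades plus Aplocheilus, and
    diapause-skipped N. furzeri replicates."""
    rows: list[SampleMeta] = []

    def add(species, clade, annual, status, n):
        for r in range(1, n + 1):
            rows.append(
                SampleMeta(
                    sample_id=f"{species}_{status}_{r}",
                    species=species,
                    clade=clade,
                    annual=annual,
                    status=status,
                    replicate=r,
                )
            )

    add("Nothobranchius_furzeri", "africa_east", True, "diapause", 5)
    add("Austrofundulus_leohoignei", "south_america", True, "diapause", 2)
    add("Callopanchax_occidentalis", "africa_west", True, "diapause", 1)
    add("Aphyosemion_striatum", "africa_east", False, "normal_development", 4)
    add("Rivulus_cylindraceus", "south_america", False, "normal_development", 1)
    add("Epiplatys_dageti", "africa_west", False, "normal_development", 1)
    add("Aplocheilus_lineatus", "india", False, "normal_development", 1)
    add("Nothobranchius_furzeri", "africa_east", True, "diapause_skipped", n_skip)
    return rows


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    created: list[Path] = []

    def emit(stage: str, path: Path) -> None:
        created.append(path)
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    def run_stage(name: str, fn):
        before = list(created)
        try:
            return fn()
        except Exception as exc:  # cleanup partial outputs of this stage
            for p in created[len(before):]:
                p.unlink(missing_ok=True)
            raise StageError(name, exc) from exc

    # --- stage 0: catalog + metadata -------------------------------------
    def stage_catalog():
        catalog = simulate.synthetic_catalog(
            n_loci=config.n_loci, seed=_stage_seed(config.seed, 0)
        )
        io.write_catalog(catalog, out / "hairpins.gff3", out / "hairpins.fa")
        meta = _study_metadata()
        io.write_metadata(meta, out / "samples.tsv")
        emit("catalog", out / "hairpins.fa")
        emit("catalog", out / "hairpins.gff3")
        emit("catalog", out / "samples.tsv")
        return catalog, meta

    catalog, meta = run_stage("catalog", stage_catalog)
    designs = standard_designs(meta)
    manifest["stages"]["catalog"] = {"n_loci": len(catalog), "n_samples": len(meta)}

    # --- stage 1: planted counts -> FASTQ -> quantification --------------
    def stage_quant():
        dia = sorted(s.sample_id for s in meta if s.status == "diapause")
        nonann = sorted(s.sample_id for s in meta if not s.annual)
        skipped = sorted(s.sample_id for s in meta if s.status == "diapause_skipped")
        design = ComparisonDesign("large_interspecies", dia, nonann)
        cfg = simulate.CountSimConfig(
            n_loci=config.n_loci,
            n_a=len(dia),
            n_b=len(nonann),
            baseline_log2_mean=config.baseline_log2_mean,
            baseline_log2_sd=config.baseline_log2_sd,
            planted_dem_fraction=config.planted_dem_fraction,
            planted_lfc=config.planted_lfc,
            planted_switch_loci=config.planted_switch_loci,
            switch_mu=2.0**config.baseline_log2_mean,
            seed=_stage_seed(config.seed, 1),
        )
        planted, truth, _ = simulate.simulate_counts(cfg, design, extra_ids=skipped)
        # catalog loci stand in for the simulated loci (same cardinality)
        locus_map = {
            f"mir-sim-{i+1}": e.locus_id for i, e in enumerate(catalog.entries)
        }
        fastq_dir = out / "fastq"
        fastq_dir.mkdir(exist_ok=True)
        paths = {}
        for j, sid in enumerate(planted.sample_ids):
            abund = {
                (locus_map[l], arm): int(planted.counts[i, j])
                for i, (l, arm) in enumerate(planted.arm_ids)
            }
            fq = fastq_dir / f"{sid}.fastq"
            simulate.simulate_small_rna_fastq(
                catalog, abund, fq, seed=_stage_seed(config.seed, 100 + j)
            )
            emit("quant", fq)
            paths[sid] = fq
        policy = quant.AssignmentPolicy(
            max_mismatches=config.max_mismatches, seed=_stage_seed(config.seed, 2)
        )
        matrix, qc = quant.quantify(paths, catalog, policy=policy)
        io.write_counts(matrix, out / "counts.tsv")
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        emit("quant", out / "counts.tsv")
        emit("quant", out / "qc.tsv")
        truth_mapped = simulate.PlantedTruth(
            dem_arm_ids={
                (locus_map[l], a): v for (l, a), v in truth.dem_arm_ids.items()
            },
            switch_locus_ids=[locus_map[l] for l in truth.switch_locus_ids],
        )
        simulate.write_truth_tsv(truth_mapped, out / "truth.tsv")
        emit("quant", out / "truth.tsv")
        return matrix, qc

    matrix, qc = run_stage("quant", stage_quant)
    manifest["stages"]["quant"] = {
        "reads_in": int(qc.reads_in.sum()),
        "assigned": int(qc.assigned.sum()),
    }

    # --- stage 2: differential expression --------------------------------
    de_results = {}

    def stage_de():
        for name, design in designs.items():
            res = diffexpr.run_comparison(
                matrix, meta, design, activity_threshold=config.activity
            )
            path = out / f"de_{name}.tsv"
            res.write_tsv(path)
            emit("de", path)
            de_results[name] = res
        return de_results

    run_stage("de", stage_de)
    manifest["stages"]["de"] = {
        name: int(res.significant.sum()) for name, res in de_results.items()
    }

    # --- stage 3: arm switches -------------------------------------------
    def stage_switch():
        calls, excluded = armswitch.detect_switches(
            matrix, meta, designs["large_interspecies"], sig_level=config.alpha
        )
        df = armswitch.switch_frame(calls)
        df.to_csv(out / "arm_switches.tsv", sep="\t", index=False)
        emit("armswitch", out / "arm_switches.tsv")
        return calls

    calls = run_stage("armswitch", stage_switch)
    manifest["stages"]["armswitch"] = {
        "n_switches": int(sum(c.is_switch for c in calls))
    }

    # --- stage 4: convergence --------------------------------------------
    def stage_converge():
        res_i = de_results["large_interspecies"]
        info: dict = {}
        if "selected_interspecies" in de_results:
            a = convergence.SignedSet.from_de("comparison_I", res_i)
            b = convergence.SignedSet.from_de(
                "comparison_III", de_results["selected_interspecies"]
            )
            background = int(res_i.active.sum())
            rep = convergence.signed_overlap(a, b, background)
            info["overlap"] = {
                "concordant": rep.n_concordant,
                "discordant": rep.n_discordant,
                "p_value": rep.p_value,
            }
        dem_ids = list(res_i.frame()[lambda d: d.significant].arm_id)
        sf = diffexpr.size_factors(matrix)
        if len(dem_ids) >= 2:
            scores, var_frac = convergence.pca_ordination(matrix, sf, dem_ids)
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            emit("converge", out / "pca_scores.tsv")
            info["pca_var_frac"] = [float(v) for v in var_frac[:2]]
        summary = convergence.per_species_active_summary(
            matrix, meta, catalog, sf,
            reference_species="Nothobranchius_furzeri",
            threshold=config.activity,
        )
        summary.to_csv(out / "active_summary.tsv", sep="\t", index=False)
        emit("converge", out / "active_summary.tsv")
        return info

    manifest["stages"]["converge"] = run_stage("converge", stage_converge)

    # --- stage 5: target enrichment --------------------------------------
    def stage_enrich():
        from .enrichment import enrich_per_mirna

        rng = np.random.default_rng(_stage_seed(config.seed, 5))
        genes = [f"gene{i+1}" for i in range(config.n_genes)]
        degs = list(rng.choice(genes, size=config.n_degs, replace=False))
        res_i = de_results["large_interspecies"]
        dem_ids = list(res_i.frame()[lambda d: d.significant].arm_id)
        target_map = {}
        for k, dem in enumerate(dem_ids):
            if k == 0 and degs:
                # one DEM with targets drawn mostly from the DEGs
                n_in = min(len(degs), int(0.8 * config.targets_per_mirna))
                picked = list(rng.choice(degs, size=n_in, replace=False))
                picked += list(
                    rng.choice(genes, size=config.targets_per_mirna - n_in,
                               replace=False)
                )
                target_map[dem] = set(picked)
            else:
                target_map[dem] = set(
                    rng.choice(genes, size=config.targets_per_mirna, replace=False)
                )
        table = enrich_per_mirna(dem_ids, target_map, degs, genes)
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        emit("enrich", out / "enrichment.tsv")
        return {"n_tested": len(table),
                "n_significant": int(table.significant.sum()) if len(table) else 0}

    manifest["stages"]["enrich"] = run_stage("enrich", stage_enrich)

    # --- stage 6: copy number --------------------------------------------
    def stage_mir430():
        estimates = []
        rows = []
        genera = [("Nothobranchius", True, config.copies_annual),
                  ("Aphyosemion", False, config.copies_nonannual)]
        fastq_dir = out / "genome_fastq"
        fastq_dir.mkdir(exist_ok=True)
        k = 0
        for genus, annual, copies in genera:
            for i in range(config.n_species_per_group):
                species = f"{genus}_sp{i+1}"
                cfg = simulate.GenomeSimConfig(
                    genome_length=config.genome_length,
                    motifs=copynumber.MIR430_MOTIFS[:1],
                    copies_per_motif=copies,
                    read_length=config.read_length,
                    coverage=config.coverage,
                    seed=_stage_seed(config.seed, 200 + k),
                )
                fq = fastq_dir / f"{species}.fastq"
                simulate.simulate_genome_reads(cfg, fq, species=species)
                emit("mir430", fq)
                h, l = copynumber.scan_reads(
                    fq, copynumber.MotifSet(), max_edits=config.max_edits
                )
                est = copynumber.estimate_copies(
                    copynumber.CopyNumberInputs(
                        species=species, genus=genus, annual=annual,
                        h=h, l=float(l), g=float(config.genome_length),
                    )
                )
                estimates.append(est)
                rows.append(
                    {"species": species, "genus": genus, "annual": annual,
                     "h": h, "l": l, "g": config.genome_length,
                     "copies": est.copies, "poisson_se": est.poisson_se,
                     "planted": copies}
                )
                k += 1
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "copy_number.tsv", sep="\t", index=False)
        emit("mir430", out / "copy_number.tsv")
        tests = copynumber.compare_groups(
            estimates,
            {"nothobranchius_vs_aphyosemion": (("Nothobranchius",), ("Aphyosemion",))},
        )
        return {
            name: {"W": t.statistic, "p_value": t.p_value}
            for name, t in tests.items()
        }

    manifest["stages"]["mir430"] = run_stage("mir430", stage_mir430)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
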