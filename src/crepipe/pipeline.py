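"""End-to-end pipeline: simulate → scan → DE → compare → qPCR → report.

Each stage reads/writes the package's standard text formats, so a run is
fully reproducible from its config and seed.  Stage failures abort with
the stage name; outputs written so far are retained and the manifest is
marked FAILED.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import arraydes, compare, motif, qpcr, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True

    # motif scan
    consensus: str = motif.CRE_CONSENSUS
    exempt_positions: tuple[int, ...] = motif.CRE_EXEMPT_POSITIONS
    max_mismatches: int = motif.CRE_MAX_MISMATCHES
    promoter_window: tuple[int, int] = (-300, 15)
    dedupe_overlap: bool = False

    # DE thresholds
    fdr: float = 0.01
    lfc: float = 0.5
    strong_lfc: float = 1.0

    # inputs (ignored when simulate=True; generated paths are used instead)
    genome: str | None = None
    annotations: str | None = None
    intensities: str | None = None
    design: str | None = None
    presence: str | None = None
    ct_table: str | None = None
    reference_gene: str = "gyrA"
    qpcr_strain: str | None = None

    # simulation scale
    sim_genome_length: int = 200_000
    sim_n_genes: int = 300
    sim_n_promoter_plants: int = 20
    sim_pi0: float = 0.85
    sim_rho: float = 0.4
    sim_d0: float = 4.0
    sim_s0_2: float = 0.05
    sim_dye_effect: float = 0.2

    def __post_init__(self) -> None:
        if self.fdr <= 0 or self.lfc <= 0 or self.strong_lfc <= 0:
            raise ValueError("thresholds must be positive")
        lo, hi = self.promoter_window
        if lo >= hi:
            raise ValueError("promoter window min must be < max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "promoter_window" in raw:
            raw["promoter_window"] = tuple(raw["promoter_window"])
        if "exempt_positions" in raw:
            raw["exempt_positions"] = tuple(raw["exempt_positions"])
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _simulate_inputs(cfg: RunConfig, out: Path, manifest: dict) -> dict:
    rng = np.random.default_rng(cfg.seed)
    pattern = motif.parse_consensus(cfg.consensus, cfg.exempt_positions, cfg.max_mismatches)
    genome = simulate.simulate_genome(cfg.sim_genome_length, seed=rng)
    anns = simulate.simulate_annotations(cfg.sim_n_genes, cfg.sim_genome_length, seed=rng)
    loci = [a.locus for a in anns]

    spots, design, truth = simulate.simulate_array_experiment(
        loci=loci,
        pi0=cfg.sim_pi0,
        rho=cfg.sim_rho,
        d0=cfg.sim_d0,
        s0_2=cfg.sim_s0_2,
        dye_effect=cfg.sim_dye_effect,
        seed=rng,
    )
    # plant cre-like sites upstream of genes that are up-regulated in every strain
    beta_wide = truth.true_log2fc.pivot(index="locus", columns="strain", values="beta")
    common_up = [l for l in beta_wide.index if (beta_wide.loc[l] > 0).all()]
    plan, targets = [], []
    by_locus = {a.locus: a for a in anns}
    taken: list[tuple[int, int]] = []
    for l in common_up[: cfg.sim_n_promoter_plants]:
        ann = by_locus[l]
        rel = -int(rng.integers(20, 160))
        pos = simulate.promoter_plant_position(ann, rel)
        if pos < 0 or pos + len(pattern) > len(genome):
            continue
        if any(pos < e and pos + len(pattern) > s for s, e in taken):
            continue
        taken.append((pos, pos + len(pattern)))
        plan.append((pos, ann.strand, int(rng.integers(0, 3)), False))
        targets.append(l)
    genome, motif_truth = simulate.plant_motifs(
        genome, plan, pattern, seed=rng, target_loci=targets
    )
    truth.planted_motifs = motif_truth.planted_motifs
    truth.accidental_hits = motif_truth.accidental_hits

    genome_path = out / "genome.fasta"
    motif.write_genome_fasta({"chr": genome}, genome_path)
    ann_path = out / "annotations.tsv"
    motif.write_annotations_tsv(anns, ann_path)
    spots_path = out / "intensities.tsv"
    spots.to_csv(spots_path, sep="\t", index=False)
    design_path = out / "design.tsv"
    design.to_csv(design_path, sep="\t", index=False)

    qpcr_strain = cfg.qpcr_strain or design["strain"].iloc[-1]
    strain_beta = (
        truth.true_log2fc[truth.true_log2fc["strain"] == qpcr_strain]
        .set_index("locus")["beta"]
    )
    reg = strain_beta[strain_beta != 0]
    genes = list(reg.index[:10])
    ct = simulate.simulate_qpcr(
        reg.to_dict(), genes, reference_gene=cfg.reference_gene, seed=rng
    )
    ct_path = out / "ct.tsv"
    ct.to_csv(ct_path, sep="\t", index=False)

    truth_paths = simulate.write_truth(truth, out / "truth")
    manifest["inputs"] = {
        "genome": str(genome_path),
        "annotations": str(ann_path),
        "intensities": str(spots_path),
        "design": str(design_path),
        "ct_table": str(ct_path),
        "truth": truth_paths,
    }
    return {
        "genome": str(genome_path),
        "annotations": str(ann_path),
        "intensities": str(spots_path),
        "design": str(design_path),
        "ct_table": str(ct_path),
        "qpcr_strain": qpcr_strain,
    }


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Run all applicable stages; returns the manifest dict.

    Stages whose inputs are absent are skipped (recorded in the manifest);
    any stage exception aborts with a :class:`StageError` after writing a
    FAILED marker into the manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "outputs": {}, "skipped": [], "summary": {}}
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; use force=True to overwrite")

    stage = "setup"
    try:
        inputs = {
            "genome": cfg.genome,
            "annotations": cfg.annotations,
            "intensities": cfg.intensities,
            "design": cfg.design,
            "ct_table": cfg.ct_table,
            "qpcr_strain": cfg.qpcr_strain,
        }
        if cfg.simulate:
            stage = "simulate"
            inputs = _simulate_inputs(cfg, out, manifest)

        pattern = motif.parse_consensus(
            cfg.consensus, cfg.exempt_positions, cfg.max_mismatches
        )

        promoter_hits = []
        anns = []
        if inputs["genome"]:
            stage = "scan"
            genome = motif.read_genome_fasta(inputs["genome"])
            hits = motif.scan(genome, pattern, dedupe_overlap=cfg.dedupe_overlap)
            bed_path = out / "cre_hits.bed"
            motif.write_hits_bed(hits, bed_path)
            manifest["outputs"]["cre_hits_bed"] = str(bed_path)
            manifest["summary"]["n_hits"] = len(hits)
            if inputs["annotations"]:
                anns = motif.read_annotations(inputs["annotations"])
                promoter_hits = motif.map_to_promoters(
                    hits,
                    anns,
                    window=cfg.promoter_window,
                    contig_lengths={c: len(s) for c, s in genome.items()},
                )
                ptable = out / "promoter_hits.tsv"
                motif.write_promoter_table(promoter_hits, ptable)
                manifest["outputs"]["promoter_hits"] = str(ptable)
                manifest["summary"]["n_promoter_hits"] = len(promoter_hits)
        else:
            manifest["skipped"].append("scan")

        results = {}
        if inputs["intensities"] and inputs["design"]:
            stage = "de"
            spots = arraydes.read_intensities(inputs["intensities"])
            design = arraydes.read_design(inputs["design"])
            results = arraydes.de_per_strain(
                spots, design, fdr=cfg.fdr, lfc=cfg.lfc, strong_lfc=cfg.strong_lfc
            )
            manifest["outputs"]["de_results"] = arraydes.write_results(results, out)
            manifest["summary"]["regulated_per_strain"] = {
                s: int((df["class"] != "unchanged").sum()) for s, df in results.items()
            }
        else:
            manifest["skipped"].append("de")

        if len(results) >= 2:
            stage = "compare"
            presence = (
                pd.read_csv(cfg.presence, sep="\t") if cfg.presence else None
            )
            venn = compare.common_regulated(results, presence)
            manifest["outputs"].update(compare.write_venn_summary(venn, out))
            manifest["summary"]["venn"] = {
                "common_up": len(venn.common_up),
                "common_down": len(venn.common_down),
                "discordant": len(venn.discordant),
            }
            cats = compare.categorize(results, {a.locus: a.category for a in anns})
            cat_path = out / "category_counts.tsv"
            cats.to_csv(cat_path, sep="\t", index=False)
            manifest["outputs"]["category_counts"] = str(cat_path)
        else:
            manifest["skipped"].append("compare")
            venn = None

        if inputs["ct_table"] and results:
            stage = "qpcr"
            ct = qpcr.read_ct_table(inputs["ct_table"])
            qres = qpcr.delta_ct_log2fc(ct, cfg.reference_gene)
            qpath = out / "qpcr_results.tsv"
            qres.to_csv(qpath, sep="\t", index=False)
            manifest["outputs"]["qpcr_results"] = str(qpath)
            strain = inputs.get("qpcr_strain") or list(results)[0]
            arr = results[strain].set_index("locus")["log2fc"].dropna().to_dict()
            manifest["summary"]["qpcr_concordance"] = qpcr.concordance(qres, arr)
        else:
            manifest["skipped"].append("qpcr")

        if promoter_hits and results:
            stage = "report"
            up_any = {
                locus
                for df in results.values()
                for locus in df.loc[df["class"] == "up", "locus"]
            }
            rows = [
                {
                    "locus": p.locus,
                    "sequence": p.hit.matched_seq,
                    "position": p.rel_position,
                    "mismatches": p.hit.mismatch_count,
                }
                for p in promoter_hits
                if p.locus in up_any
            ]
            report = pd.DataFrame(
                rows, columns=["locus", "sequence", "position", "mismatches"]
            )
            rpath = out / "upregulated_cre_report.tsv"
            report.to_csv(rpath, sep="\t", index=False)
            manifest["outputs"]["upregulated_cre_report"] = str(rpath)
            manifest["summary"]["n_upregulated_with_cre"] = int(report["locus"].nunique())
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise StageError(stage, exc) from exc

    manifest["status"] = "OK"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
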