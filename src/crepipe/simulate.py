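"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the structure of a carbon-source shift experiment
in a small bacterium: an i.i.d. background genome with cre-like 14-mers
planted at controlled mismatch counts and strands, non-overlapping CDS
annotations with upstream promoter windows, a multi-strain two-color
array experiment (three biological parallels, three probe replicates per
gene per array, one dye-swap hybridization per strain, gene variances
from a scaled-inverse-chi-square prior, within-array probe-replicate
correlation), and qRT-PCR CT tables consistent with the array truth.

Every generator is deterministic under its seed, and each returns the
ground truth needed for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import (
    ConsensusPattern,
    GeneAnnotation,
    MotifHit,
    cre_pattern,
    reverse_complement,
    scan,
)

_BASES = np.array(list("ACGT"))

DEFAULT_STRAINS = ("23K", "MF1053", "LS25")


@dataclass(frozen=True)
class PlantedMotif:
    contig: str
    start: int  # 0-based, forward-strand footprint start
    strand: str
    sequence: str  # as read on the planted strand
    mismatch_count: int
    center_violation: bool
    target_locus: str | None = None


@dataclass
class TruthSet:
    """Ground truth emitted by the generators."""

    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    accidental_hits: list[MotifHit] = field(default_factory=list)
    true_log2fc: pd.DataFrame | None = None  # columns: locus, strain, beta
    true_variance: pd.DataFrame | None = None  # columns: locus, sigma2
    rho: float | None = None
    d0: float | None = None
    s0_2: float | None = None

    def de_labels(self) -> pd.DataFrame:
        """Per (locus, strain): up / down / unchanged from the planted beta."""
        df = self.true_log2fc.copy()
        df["label"] = np.where(
            df["beta"] > 0, "up", np.where(df["beta"] < 0, "down", "unchanged")
        )
        return df


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genome(length: int, gc_fraction: float = 0.41, seed=0) -> str:
    """I.i.d. background sequence at the requested GC content.

    The default GC of 0.41 matches a low-GC Gram-positive genome.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = _rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


def sample_consensus_instance(pattern: ConsensusPattern, rng) -> str:
    """Draw one sequence conforming exactly to the consensus."""
    return "".join(rng.choice(sorted(allowed)) for allowed in pattern.positions)


def mutate_instance(
    seq: str,
    pattern: ConsensusPattern,
    n_mismatches: int,
    center_violation: bool,
    rng,
) -> str:
    """Substitute disallowed bases at conserved positions.

    ``n_mismatches`` substitutions are placed at distinct conserved,
    non-exempt positions; when ``center_violation`` one exempt position is
    additionally broken.
    """
    out = list(seq)
    candidates = [
        i
        for i, (c, e) in enumerate(zip(pattern.conserved_mask, pattern.center_exempt_mask))
        if c and not e
    ]
    if n_mismatches > len(candidates):
        raise ValueError("more mismatches requested than mutable conserved positions")
    for i in rng.choice(len(candidates), size=n_mismatches, replace=False):
        pos = candidates[int(i)]
        disallowed = sorted(set("ACGT") - pattern.positions[pos])
        out[pos] = disallowed[int(rng.integers(len(disallowed)))]
    if center_violation:
        exempt = [i for i, e in enumerate(pattern.center_exempt_mask) if e]
        pos = exempt[int(rng.integers(len(exempt)))]
        disallowed = sorted(set("ACGT") - pattern.positions[pos])
        out[pos] = disallowed[int(rng.integers(len(disallowed)))]
    return "".join(out)


def plant_motifs(
    genome: str,
    plan: Sequence[tuple[int, str, int, bool]],
    pattern: ConsensusPattern | None = None,
    seed=0,
    contig: str = "chr",
    target_loci: Sequence[str | None] | None = None,
) -> tuple[str, TruthSet]:
    """Overwrite the background with consensus-derived 14-mers.

    ``plan`` lists (position, strand, n_mismatches, center_violation) per
    planted site; footprints must not overlap each other.  After planting,
    the sequence is re-scanned and background windows that happen to match
    are recorded as accidental hits in the truth set.
    """
    pattern = pattern or cre_pattern()
    rng = _rng(seed)
    m = len(pattern)
    seq = list(genome)
    footprints: list[tuple[int, int]] = []
    planted: list[PlantedMotif] = []
    if target_loci is None:
        target_loci = [None] * len(plan)
    for (pos, strand, n_mm, violate), locus in zip(plan, target_loci):
        if pos < 0 or pos + m > len(seq):
            raise ValueError(f"planted footprint {pos} out of genome bounds")
        for s, e in footprints:
            if pos < e and pos + m > s:
                raise ValueError(f"planted footprints overlap at {pos}")
        footprints.append((pos, pos + m))
        inst = mutate_instance(sample_consensus_instance(pattern, rng), pattern, n_mm, violate, rng)
        fwd = inst if strand == "+" else reverse_complement(inst)
        seq[pos : pos + m] = list(fwd)
        planted.append(
            PlantedMotif(
                contig=contig,
                start=pos,
                strand=strand,
                sequence=inst,
                mismatch_count=n_mm,
                center_violation=violate,
                target_locus=locus,
            )
        )
    new_genome = "".join(seq)
    hits = scan({contig: new_genome}, pattern)
    planted_keys = {(p.start, p.strand) for p in planted}
    accidental = [h for h in hits if (h.start, h.strand) not in planted_keys]
    truth = TruthSet(planted_motifs=planted, accidental_hits=accidental)
    return new_genome, truth


def simulate_annotations(
    n_genes: int,
    genome_length: int,
    mean_igr: int = 150,
    min_igr: int = 50,
    seed=0,
    contig: str = "chr",
    categories: Sequence[str] = (
        "carbohydrate transport and metabolism",
        "nucleotide transport and metabolism",
        "transcription",
        "translation",
        "unknown",
    ),
) -> list[GeneAnnotation]:
    """Non-overlapping CDSs on both strands with intergenic gaps ≥ min_igr.

    Gaps are min_igr plus a geometric excess with the requested mean; CDS
    lengths are uniform multiples of 3 in 300..900.  Generation stops
    early if the genome is exhausted.
    """
    rng = _rng(seed)
    anns: list[GeneAnnotation] = []
    pos = 1
    for i in range(n_genes):
        gap = min_igr + int(rng.geometric(1.0 / max(mean_igr - min_igr, 1))) - 1
        start = pos + gap
        length = int(rng.integers(100, 301)) * 3
        end = start + length - 1
        if end > genome_length - min_igr:
            break
        locus = f"GENE{i + 1:04d}"
        anns.append(
            GeneAnnotation(
                locus=locus,
                name=locus.lower(),
                contig=contig,
                strand="+" if rng.random() < 0.5 else "-",
                cds_start=start,
                cds_end=end,
                category=str(rng.choice(list(categories))),
            )
        )
        pos = end + 1
    return anns


def promoter_plant_position(ann: GeneAnnotation, rel_position: int, motif_len: int = 14) -> int:
    """0-based genome offset at which to plant a motif so its 5'-most base
    on the gene's coding strand sits at ``rel_position`` (no-zero)."""
    if rel_position == 0:
        raise ValueError("rel_position 0 does not exist")
    ts = ann.translation_start
    off = rel_position if rel_position < 0 else rel_position - 1
    if ann.strand == "+":
        return ts + off - 1
    return ts - off - motif_len


# ---------------------------------------------------------------------------
# Array experiment


def simulate_array_experiment(
    n_genes: int = 2000,
    strains: Sequence[str] = DEFAULT_STRAINS,
    pi0: float = 0.85,
    effect_range: tuple[float, float] = (0.5, 4.0),
    d0: float = 4.0,
    s0_2: float = 0.05,
    rho: float = 0.4,
    dye_effect: float = 0.2,
    seed=0,
    n_bio_reps: int = 3,
    n_probe_reps: int = 3,
    dye_swap: bool = True,
    exclude_rate: float = 0.01,
    common_fraction: float = 0.5,
    loci: Sequence[str] | None = None,
    effects: pd.DataFrame | None = None,
    base_a: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthSet]:
    """Two-channel spot intensities + design for a multi-strain experiment.

    Per gene g: β_g = 0 with probability ``pi0``, else ±Uniform over
    ``effect_range``; of the non-null genes a ``common_fraction`` share
    the same β in every strain, the rest are regulated in one strain only.
    Gene variances σ_g² ~ s0_2·d0/χ²_d0.  Per array a and probe replicate
    r the oriented log-ratio is β_g + b_ga + e_gar with array-level b and
    spot-level e splitting σ_g² as rho/(1−rho); a constant dye bias is
    added on the measured (unoriented) scale, so it enters +dye_effect on
    non-swapped and −dye_effect on swapped arrays after orientation.
    Intensities are reconstructed from (M, A) with A ~ Normal(base_a, 1);
    ``exclude_rate`` of spots are flagged excluded.

    ``effects`` (columns locus, strain, beta) overrides the random truth.
    """
    rng = _rng(seed)
    if loci is None:
        loci = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    loci = list(loci)
    n_genes = len(loci)
    strains = list(strains)

    if effects is None:
        n_nonnull = int(round((1.0 - pi0) * n_genes))
        nonnull_idx = rng.choice(n_genes, size=n_nonnull, replace=False)
        n_common = int(round(common_fraction * n_nonnull))
        beta = pd.DataFrame(0.0, index=pd.Index(loci, name="locus"), columns=strains)
        mags = rng.uniform(effect_range[0], effect_range[1], size=n_nonnull)
        signs = rng.choice([-1.0, 1.0], size=n_nonnull)
        for j, gi in enumerate(nonnull_idx):
            b = signs[j] * mags[j]
            if j < n_common:
                beta.iloc[gi, :] = b
            else:
                beta.iloc[gi, int(rng.integers(len(strains)))] = b
        true_fc = beta.reset_index().melt(id_vars="locus", var_name="strain", value_name="beta")
    else:
        beta = effects.pivot(index="locus", columns="strain", values="beta").reindex(
            index=loci, columns=strains, fill_value=0.0
        ).fillna(0.0)
        true_fc = beta.reset_index().melt(id_vars="locus", var_name="strain", value_name="beta")

    sigma2 = s0_2 * d0 / rng.chisquare(d0, size=n_genes)
    true_var = pd.DataFrame({"locus": loci, "sigma2": sigma2})

    design_rows = []
    spot_rows = []
    for strain in strains:
        array_specs = [(f"{strain}_a{r}", r, False) for r in range(1, n_bio_reps + 1)]
        if dye_swap:
            array_specs.append((f"{strain}_a1_swap", 1, True))
        for array_id, bio_rep, swapped in array_specs:
            ribose_channel = "ch1" if swapped else "ch2"
            design_rows.append(
                {
                    "array_id": array_id,
                    "strain": strain,
                    "bio_replicate": bio_rep,
                    "ribose_channel": ribose_channel,
                    "is_dye_swap": int(swapped),
                }
            )
            sign = -1.0 if swapped else 1.0
            b_ga = rng.normal(0.0, np.sqrt(rho * sigma2))
            e = rng.normal(
                0.0, np.sqrt((1.0 - rho) * sigma2)[:, None], size=(n_genes, n_probe_reps)
            )
            m_oriented = beta[strain].to_numpy()[:, None] + b_ga[:, None] + e
            r_measured = sign * m_oriented + dye_effect
            a_vals = rng.normal(base_a, 1.0, size=(n_genes, n_probe_reps))
            ch2 = 2.0 ** (a_vals + r_measured / 2.0)
            ch1 = 2.0 ** (a_vals - r_measured / 2.0)
            excluded = rng.random(size=(n_genes, n_probe_reps)) < exclude_rate
            for rep in range(n_probe_reps):
                spot_rows.append(
                    pd.DataFrame(
                        {
                            "array_id": array_id,
                            "spot_id": [f"{array_id}_s{gi}_{rep}" for gi in range(n_genes)],
                            "probe_id": [f"{l}_p{rep + 1}" for l in loci],
                            "locus": loci,
                            "ch1": ch1[:, rep],
                            "ch2": ch2[:, rep],
                            "excluded": excluded[:, rep].astype(int),
                        }
                    )
                )
    spots = pd.concat(spot_rows, ignore_index=True)
    design = pd.DataFrame(design_rows)
    truth = TruthSet(
        true_log2fc=true_fc, true_variance=true_var, rho=rho, d0=d0, s0_2=s0_2
    )
    return spots, design, truth


def simulate_qpcr(
    effects: Mapping[str, float],
    genes: Sequence[str],
    reference_gene: str = "gyrA",
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed=0,
    base_ct_range: tuple[float, float] = (18.0, 26.0),
) -> pd.DataFrame:
    """CT table consistent with the array truth.

    For each target gene the ribose-condition CT is lowered by the true
    log2 effect (one cycle per log2 unit); the reference gene is flat
    across conditions.  Gaussian cycle noise of ``noise_sd`` is added to
    every measurement.
    """
    rng = _rng(seed)
    rows = []
    all_genes = list(genes) + [reference_gene]
    base = {g: rng.uniform(*base_ct_range) for g in all_genes}
    for gene in all_genes:
        b = float(effects.get(gene, 0.0)) if gene != reference_gene else 0.0
        for cond in ("glucose", "ribose"):
            shift = -b if cond == "ribose" else 0.0
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{cond}_{rep}",
                        "condition": cond,
                        "gene": gene,
                        "replicate": rep,
                        "ct": base[gene] + shift + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truth round-trip I/O


def write_truth(truth: TruthSet, out_dir) -> dict[str, str]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if truth.planted_motifs:
        df = pd.DataFrame([vars(p) for p in truth.planted_motifs])
        df["target_locus"] = df["target_locus"].fillna("")
        path = out_dir / "truth_planted_motifs.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths["planted_motifs"] = str(path)
    if truth.true_log2fc is not None:
        path = out_dir / "truth_log2fc.tsv"
        truth.true_log2fc.to_csv(path, sep="\t", index=False)
        paths["true_log2fc"] = str(path)
    if truth.true_variance is not None:
        path = out_dir / "truth_variance.tsv"
        truth.true_variance.to_csv(path, sep="\t", index=False)
        paths["true_variance"] = str(path)
    scalars = {"rho": truth.rho, "d0": truth.d0, "s0_2": truth.s0_2}
    path = out_dir / "truth_params.json"
    with open(path, "w") as fh:
        json.dump(scalars, fh, indent=2)
    paths["params"] = str(path)
    return paths


def read_truth(out_dir) -> TruthSet:
    out_dir = Path(out_dir)
    truth = TruthSet()
    p = out_dir / "truth_planted_motifs.tsv"
    if p.exists():
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
        truth.planted_motifs = [
            PlantedMotif(
                contig=str(r.contig),
                start=int(r.start),
                strand=str(r.strand),
                sequence=str(r.sequence),
                mismatch_count=int(r.mismatch_count),
                center_violation=bool(r.center_violation),
                target_locus=str(r.target_locus) or None,
            )
            for r in df.itertuples(index=False)
        ]
    p = out_dir / "truth_log2fc.tsv"
    if p.exists():
        truth.true_log2fc = pd.read_csv(p, sep="\t")
    p = out_dir / "truth_variance.tsv"
    if p.exists():
        truth.true_variance = pd.read_csv(p, sep="\t")
    p = out_dir / "truth_params.json"
    if p.exists():
        with open(p) as fh:
            scalars = json.load(fh)
        truth.rho = scalars.get("rho")
        truth.d0 = scalars.get("d0")
        truth.s0_2 = scalars.get("s0_2")
    return truth
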