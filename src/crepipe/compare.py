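"""Cross-strain comparison of regulated gene sets.

Combines per-strain differential-expression calls into Venn-region counts
and common regulated gene lists, taking gene presence into account: a
comparative-genome-hybridization style presence matrix marks each locus in
each strain as present (P), divergent or absent (D), or uncertain (U).
Loci that are divergent/absent or uncertain in any strain are excluded
from the common set, and loci called up in some strains but down in
others are counted as discordant rather than common.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

PRESENT = "P"
DIVERGENT = "D"
UNCERTAIN = "U"


def presence_matrix(
    presence: pd.DataFrame | None,
    loci: Sequence[str],
    strains: Sequence[str],
    uncertain_as_present: bool = False,
) -> pd.DataFrame:
    """Build a locus × strain presence table, defaulting to present.

    ``presence`` (optional) has columns locus, strain, status ∈ {P, D, U}.
    """
    mat = pd.DataFrame(PRESENT, index=pd.Index(sorted(set(loci)), name="locus"), columns=list(strains))
    if presence is not None:
        bad = set(presence["status"]) - {PRESENT, DIVERGENT, UNCERTAIN}
        if bad:
            raise ValueError(f"invalid presence status values: {sorted(bad)}")
        for row in presence.itertuples(index=False):
            if row.locus in mat.index and row.strain in mat.columns:
                mat.loc[row.locus, row.strain] = row.status
    if uncertain_as_present:
        mat = mat.replace(UNCERTAIN, PRESENT)
    return mat


@dataclass
class VennSummary:
    """3-set (or k-set) Venn of regulated genes across strains."""

    strains: tuple[str, ...]
    #: region key (frozenset of strains regulating the locus) → {"up": [...], "down": [...]}
    regions: dict[frozenset, dict[str, list[str]]]
    common_up: list[str]
    common_down: list[str]
    discordant: list[str]
    excluded_absent: list[str] = field(default_factory=list)

    def region_counts(self) -> pd.DataFrame:
        rows = []
        for key, d in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
            rows.append(
                {
                    "region": "&".join(sorted(key)),
                    "n_strains": len(key),
                    "up": len(d["up"]),
                    "down": len(d["down"]),
                }
            )
        return pd.DataFrame(rows, columns=["region", "n_strains", "up", "down"])

    @property
    def union_size(self) -> int:
        return sum(len(d["up"]) + len(d["down"]) for d in self.regions.values()) + len(
            self.discordant
        )


def common_regulated(
    results: Mapping[str, pd.DataFrame],
    presence: pd.DataFrame | None = None,
    uncertain_as_present: bool = False,
) -> VennSummary:
    """Venn summary of up/down calls across strains.

    ``results`` maps strain → per-strain results with at least columns
    locus and class.  A locus is common-up iff it is present in every
    strain and classified up in all of them (likewise common-down);
    direction-discordant loci are excluded from both common lists.
    """
    strains = tuple(results)
    calls: dict[str, dict[str, str]] = {}
    for strain, df in results.items():
        reg = df[df["class"].isin(["up", "down"])]
        for locus, cls in zip(reg["locus"], reg["class"]):
            calls.setdefault(locus, {})[strain] = cls
    mat = presence_matrix(presence, list(calls), strains, uncertain_as_present)
    regions: dict[frozenset, dict[str, list[str]]] = {}
    common_up: list[str] = []
    common_down: list[str] = []
    discordant: list[str] = []
    excluded_absent: list[str] = []
    for locus in sorted(calls):
        by_strain = calls[locus]
        dirs = set(by_strain.values())
        key = frozenset(by_strain)
        if len(dirs) > 1:
            discordant.append(locus)
            continue
        direction = dirs.pop()
        regions.setdefault(key, {"up": [], "down": []})[direction].append(locus)
        present_everywhere = all(mat.loc[locus, s] == PRESENT for s in strains)
        if key == frozenset(strains) and present_everywhere:
            (common_up if direction == "up" else common_down).append(locus)
        elif key == frozenset(strains):
            excluded_absent.append(locus)
    return VennSummary(
        strains=strains,
        regions=regions,
        common_up=common_up,
        common_down=common_down,
        discordant=discordant,
        excluded_absent=excluded_absent,
    )


def categorize(
    results: Mapping[str, pd.DataFrame], annotations: Mapping[str, str]
) -> pd.DataFrame:
    """Count regulated genes per (strain, category, direction).

    ``annotations`` maps locus → functional category; unknown loci are
    binned as "unknown".
    """
    rows = []
    for strain, df in results.items():
        reg = df[df["class"].isin(["up", "down"])]
        for locus, cls in zip(reg["locus"], reg["class"]):
            rows.append(
                {
                    "strain": strain,
                    "category": annotations.get(locus, "unknown"),
                    "direction": cls,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["strain", "category", "direction", "n"])
    return (
        pd.DataFrame(rows)
        .groupby(["strain", "category", "direction"])
        .size()
        .rename("n")
        .reset_index()
    )


def write_venn_summary(summary: VennSummary, out_dir) -> dict[str, str]:
    """Write venn_summary.tsv and common_genes.tsv; returns written paths."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    venn_path = out_dir / "venn_summary.tsv"
    summary.region_counts().to_csv(venn_path, sep="\t", index=False)
    rows = [("up", l) for l in summary.common_up] + [("down", l) for l in summary.common_down]
    rows += [("discordant", l) for l in summary.discordant]
    common_path = out_dir / "common_genes.tsv"
    pd.DataFrame(rows, columns=["direction", "locus"]).to_csv(
        common_path, sep="\t", index=False
    )
    return {"venn_summary": str(venn_path), "common_genes": str(common_path)}
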