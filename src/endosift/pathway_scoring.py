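"""Metabolic pathway completeness calls and gene-content comparison.

A reduced endosymbiont genome is characterized by which biosynthetic
pathways it retains.  Given a gene-presence table, each pathway is called
``intact`` (every gene present), ``absent`` (at or below an absence
threshold, zero genes by default) or ``incomplete`` (anything between).
Gene content between two genomes is compared per functional category as
shared / private-to-A / private-to-B counts, and assemblies are tabulated
on the genome-size-vs-GC landscape that separates reduced endosymbionts
from free-living relatives.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .seq_io import AssemblyStats

STATUS_INTACT = "intact"
STATUS_INCOMPLETE = "incomplete"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class PathwayDef:
    """A named biosynthetic pathway as an ordered gene list."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValueError(f"pathway {self.name!r} has no genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"pathway {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class PathwayStatus:
    """Completeness call for one pathway in one genome."""

    pathway: str
    status: str
    present_genes: tuple[str, ...]
    missing_genes: tuple[str, ...]
    present_fraction: float


def score_pathway(
    present: Iterable[str],
    pathway: PathwayDef,
    absence_threshold: float = 0.0,
) -> PathwayStatus:
    """Classify one pathway from the set of present gene ids.

    ``intact`` iff every pathway gene is present; ``absent`` iff the
    present fraction is <= ``absence_threshold`` (default 0: absent means
    not a single gene found); ``incomplete`` otherwise.
    """
    if not (0.0 <= absence_threshold < 1.0):
        raise ValueError("absence_threshold must be in [0, 1)")
    present_set = set(present)
    hit = tuple(g for g in pathway.gene_ids if g in present_set)
    miss = tuple(g for g in pathway.gene_ids if g not in present_set)
    frac = len(hit) / len(pathway.gene_ids)
    if frac == 1.0:
        status = STATUS_INTACT
    elif frac <= absence_threshold:
        status = STATUS_ABSENT
    else:
        status = STATUS_INCOMPLETE
    return PathwayStatus(
        pathway=pathway.name,
        status=status,
        present_genes=hit,
        missing_genes=miss,
        present_fraction=frac,
    )


def score_pathways(
    present: Iterable[str],
    pathways: Sequence[PathwayDef],
    absence_threshold: float = 0.0,
) -> list[PathwayStatus]:
    present_set = set(present)
    return [
        score_pathway(present_set, p, absence_threshold) for p in pathways
    ]


def status_table(statuses: Sequence[PathwayStatus]) -> pd.DataFrame:
    """Tabulate pathway calls, one row per pathway."""
    return pd.DataFrame(
        {
            "pathway": [s.pathway for s in statuses],
            "status": [s.status for s in statuses],
            "present_fraction": [s.present_fraction for s in statuses],
            "missing_genes": [",".join(s.missing_genes) for s in statuses],
        }
    )


def compare_gene_content(
    functions_a: Mapping[str, Iterable[str]],
    functions_b: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Shared vs private function counts per functional category.

    Missing categories count as empty sets, so the category universe is
    the union of both genomes' categories.
    """
    cats = sorted(set(functions_a) | set(functions_b))
    rows = []
    for cat in cats:
        a = set(functions_a.get(cat, ()))
        b = set(functions_b.get(cat, ()))
        rows.append(
            {
                "category": cat,
                "shared": len(a & b),
                "private_a": len(a - b),
                "private_b": len(b - a),
            }
        )
    return pd.DataFrame(rows)


def genome_landscape(
    stats: Sequence[tuple[str, AssemblyStats]],
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Genome size vs GC table, sorted by size ascending.

    ``labels`` marks each genome (e.g. ``endosymbiont`` vs ``other``), the
    split that makes reduced AT-rich symbiont genomes stand apart from
    free-living relatives on a size/composition plot.
    """
    if not stats:
        raise ValueError("no assemblies given")
    names = [name for name, _ in stats]
    if len(set(names)) != len(names):
        raise ValueError("duplicate genome names")
    rows = [
        {
            "name": name,
            "size_bp": s.total_length,
            "gc_percent": s.gc_percent,
            "label": labels.get(name, "other"),
        }
        for name, s in stats
    ]
    return pd.DataFrame(rows).sort_values("size_bp", ignore_index=True)


# ---------------------------------------------------------------------------
# presence tables and packaged pathway definitions
# ---------------------------------------------------------------------------


def presence_from_table(table: pd.DataFrame | str | Path) -> set[str]:
    """Present gene ids from a (gene_id, present 0/1) table or a plain
    one-column id list."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    if "present" in table.columns:
        return set(table.loc[table["present"].astype(int) == 1, "gene_id"])
    return set(table.iloc[:, 0])


def load_pathways(path: str | Path | None = None) -> list[PathwayDef]:
    """Pathway definitions from a YAML mapping of name -> gene list.

    Without a path, the packaged defaults ship the B-vitamin and
    amino-acid pathways relevant to a feather-louse symbiont (pantothenate
    panB/panC/panE, coenzyme A coaA-D, the His/Lys/Met/Trp biosynthesis
    gene sets, folate, biotin, riboflavin).  Every list is a documented,
    user-overridable default.
    """
    if path is None:
        source = importlib.resources.files("endosift").joinpath(
            "data", "pathways.yaml"
        )
        raw = yaml.safe_load(source.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return [
        PathwayDef(name=name, gene_ids=tuple(genes))
        for name, genes in raw.items()
    ]
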