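"""Cluster characterization: family composition, clustering VOCs, hubs.

Mirrors how detected communities are summarised for botanical reading:
per cluster, its size and share of the species set, a family histogram,
the member list, and the VOCs shared by most members ("clustering VOCs").
All degree-0 species are merged into a single pseudo-cluster labelled
"isolated" and reported last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .community import Partition
from .preprocessing import IncidenceMatrix

__all__ = [
    "ClusterReport",
    "cluster_composition",
    "clustering_vocs",
    "top_strength_nodes",
    "percent",
    "report_markdown",
]

ISOLATED_LABEL = "isolated"


def percent(part: int, total: int) -> float:
    """Share as a percentage rounded half-up to 1 decimal (28/109 → 25.7)."""
    return float(
        (Decimal(100 * part) / Decimal(total)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass
class ClusterSummary:
    label: str
    size: int
    percent: float
    families: list[tuple[str, int]]
    members: list[str]
    n_families: int


@dataclass
class ClusterReport:
    n_species: int
    clusters: list[ClusterSummary] = field(default_factory=list)


def _ordered_clusters(p: Partition, isolated: set) -> list[tuple[str, list[str]]]:
    """Clusters by descending size, the isolated pseudo-cluster always last."""
    groups: dict[int, list] = {}
    for n, c in p.membership.items():
        if n in isolated:
            continue
        groups.setdefault(c, []).append(n)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), sorted(ms)[0]))
    out = [(f"cluster {i + 1}", sorted(ms)) for i, ms in enumerate(ordered)]
    if isolated:
        out.append((ISOLATED_LABEL, sorted(isolated)))
    return out


def cluster_composition(p: Partition, families: dict[str, str],
                        isolated: set | None = None) -> ClusterReport:
    """Per-cluster size, percent share and family histogram.

    ``isolated`` names the degree-0 species to merge into the trailing
    pseudo-cluster; pass the node set from ``metrics.isolated_nodes``.
    Family histograms are sorted by descending count, then alphabetically.
    """
    isolated = set(isolated or ())
    missing = [s for s in p.membership if s not in families]
    if missing:
        raise KeyError(f"species without family annotation: {sorted(missing)[:5]}")
    total = len(p.membership)
    report = ClusterReport(n_species=total)
    for label, members in _ordered_clusters(p, isolated):
        hist: dict[str, int] = {}
        for s in members:
            hist[families[s]] = hist.get(families[s], 0) + 1
        fam_sorted = sorted(hist.items(), key=lambda kv: (-kv[1], kv[0]))
        report.clusters.append(ClusterSummary(
            label=label,
            size=len(members),
            percent=percent(len(members), total),
            families=fam_sorted,
            members=members,
            n_families=len(hist),
        ))
    return report


def clustering_vocs(p: Partition, inc: IncidenceMatrix, top_n: int = 10,
                    isolated: set | None = None,
                    chem_class_of: dict[str, str] | None = None) -> dict:
    """Per cluster, the VOCs emitted by the most members, ranked.

    For each cluster and VOC the count is the number of cluster members
    whose incidence bit is 1; VOCs emitted by nobody never appear.  Counts
    are invariant to community relabeling.
    """
    chem = chem_class_of or {}
    row_of = {s: i for i, s in enumerate(inc.species_ids)}
    unknown = [s for s in p.membership if s not in row_of]
    if unknown:
        raise KeyError(f"species absent from incidence matrix: {sorted(unknown)[:5]}")
    out: dict[str, list] = {}
    for label, members in _ordered_clusters(p, set(isolated or ())):
        counts = []
        for j, voc in enumerate(inc.voc_ids):
            c = int(sum(inc.bits[row_of[s], j] for s in members))
            if c > 0:
                counts.append((voc, c, chem.get(voc)))
        counts.sort(key=lambda t: (-t[1], t[0]))
        out[label] = counts[:top_n]
    return out


def top_strength_nodes(g, n: int = 10) -> list[tuple[str, float]]:
    """Nodes ranked by strength (descending), ties broken alphabetically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    strengths = [(node, float(g.degree(node, weight="weight"))) for node in g]
    strengths.sort(key=lambda t: (-t[1], str(t[0])))
    return strengths[:n]


def report_markdown(report: ClusterReport, vocs: dict | None = None) -> str:
    """Human-readable Markdown rendering of a cluster report."""
    lines = [f"# Community report ({report.n_species} species)", ""]
    for cl in report.clusters:
        lines.append(f"## {cl.label}: {cl.size} species ({cl.percent}%), "
                     f"{cl.n_families} families")
        fams = ", ".join(f"{f} ({c})" for f, c in cl.families[:8])
        lines.append(f"- families: {fams}")
        if vocs and cl.label in vocs and vocs[cl.label]:
            tops = ", ".join(
                f"{v} ({c}{', ' + cc if cc else ''})" for v, c, cc in vocs[cl.label][:8]
            )
            lines.append(f"- clustering VOCs: {tops}")
        lines.append(f"- members: {', '.join(cl.members)}")
        lines.append("")
    return "\n".join(lines)


def report_tsv(report: ClusterReport) -> str:
    """Cluster × family composition as TSV (cluster, family, count columns)."""
    lines = ["cluster\tsize\tpercent\tfamily\tcount"]
    for cl in report.clusters:
        for fam, c in cl.families:
            lines.append(f"{cl.label}\t{cl.size}\t{cl.percent}\t{fam}\t{c}")
    return "\n".join(lines) + "\n"
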