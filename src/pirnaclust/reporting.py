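"""Deterministic report writers: summary table, per-cluster FASTA and SVG,
and a BED6 export.

All genome coordinates in the summary and FASTA are 1-based inclusive (the
coordinate convention of the consumed mapping format); BED output converts
to 0-based half-open intervals.  Output bodies contain no timestamps, so a
rerun on identical input and configuration is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .classify import Cluster, RunConfig
from .density import DensityThresholds

SUMMARY_COLUMNS = [
    "chromosome", "start", "end", "size_nt", "hits", "normalized_hits",
    "single_copy_loci", "score_strand_bias", "score_typical_length",
    "score_t1_or_a10", "score_ntr", "score_sum", "ntr", "directionality",
    "degree_mono", "degree_bi", "split_point", "chance_probability",
    "provenance",
]


def sort_clusters(clusters: Iterable[Cluster]) -> list[Cluster]:
    """Deterministic report order: summed score desc, then chromosome, start."""
    return sorted(
        clusters, key=lambda c: (-c.scores.total, c.chromosome, c.start)
    )


def _summary_row(c: Cluster) -> str:
    fields = [
        c.chromosome, str(c.start), str(c.end), str(c.span), str(len(c.hits)),
        f"{c.ntr.normalized_hits:.4f}", str(c.single_copy_loci),
        f"{c.scores.strand_bias:.4f}", f"{c.scores.typical_length:.4f}",
        f"{c.scores.t1_or_a10:.4f}", f"{c.scores.ntr:.4f}",
        f"{c.scores.total:.4f}", f"{c.ntr.ntr:.4f}", c.directionality,
        f"{c.degree_mono:.4f}", f"{c.degree_bi:.4f}",
        str(c.split_point) if c.split_point is not None else ".",
        f"{c.combined_chance_probability:.6e}", c.provenance,
    ]
    return "\t".join(fields)


def write_summary(
    clusters: Iterable[Cluster],
    config: RunConfig,
    path: str | Path,
    thresholds: DensityThresholds | None = None,
    set_probabilities: tuple[float, float, float] | None = None,
) -> None:
    """Write the tab-separated cluster summary.

    The header documents all thresholds; the footer reports the set-level
    probabilities of 0, >=1 and >=2 mistakenly annotated clusters.
    """
    clusters = sort_clusters(clusters)
    lines = [
        f"# alpha={config.alpha:g}",
        "# min_scores=" + ",".join(
            f"{k}:{v:g}" if v is not None else f"{k}:off"
            for k, v in config.min_scores.items()
        ),
        f"# typical_length={config.typical_length[0]}-{config.typical_length[1]}",
        f"# directionality_threshold={config.directionality_threshold:g}",
        f"# composition_mode={config.composition_mode}",
        f"# rescue_max_hits="
        + (str(config.rescue_max_hits) if config.rescue_max_hits else "off"),
    ]
    if thresholds is not None:
        lo, hi = thresholds.density_range()
        lines.append(f"# min_hit_density_range={lo:.1f}-{hi:.1f} hits/kb")
        lines.append(f"# min_loci={thresholds.min_loci}")
    lines.append("\t".join(SUMMARY_COLUMNS))
    lines.extend(_summary_row(c) for c in clusters)
    if set_probabilities is not None:
        p0, p1, p2 = set_probabilities
        lines.append(
            f"# P(0 mistaken)={p0:.6g}\tP(>=1 mistaken)={p1:.6g}\t"
            f"P(>=2 mistaken)={p2:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_summary(path: str | Path) -> list[dict[str, str]]:
    """Parse a summary file back into per-cluster field dictionaries."""
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rows.append(dict(zip(header, fields)))
    return rows


def write_cluster_fasta(cluster: Cluster, path: str | Path) -> None:
    """One FASTA record per locus; titles encode position, copies and hits."""
    records = []
    for h in cluster.hits:
        records.append(
            SeqRecord(
                Seq(h.read.sequence),
                id=f"{h.chromosome}:{h.start}-{h.end}:{h.strand}",
                description=f"copies={h.read.copy_number} "
                            f"genomic_hits={h.read.genomic_hits}",
            )
        )
    with Path(path).open("w") as fh:
        seqio_write(records, fh, "fasta")


def write_bed(clusters: Iterable[Cluster], path: str | Path) -> None:
    """BED6 export (0-based half-open); mono clusters keep their main strand,
    bi- and non-directional clusters get strand "."."""
    lines = []
    for c in sort_clusters(clusters):
        name = f"piRNA_cluster_{c.chromosome}_{c.start}"
        score = min(1000, round(100 * c.scores.total))
        strand = c.main_strand if c.directionality == "mono" else "."
        lines.append(
            f"{c.chromosome}\t{c.start - 1}\t{c.end}\t{name}\t{score}\t{strand}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def render_cluster(
    cluster: Cluster,
    path: str | Path | None = None,
    normalize: bool = False,
    log_scale: bool = False,
    width: int = 800,
    height: int = 260,
) -> str:
    """Render a cluster as deterministic SVG markup.

    Loci are drawn as bars from a central line: plus-strand loci point
    upward, minus-strand loci downward.  Bar height is proportional to the
    read's copy number, optionally normalized by its number of genomic hits
    (``normalize``), max-scaled per cluster (optionally on a log scale for
    wide dynamic ranges).  Multi-copy loci (reads with more than one genomic
    hit) are red, single-copy loci black.  The top axis is cluster-relative,
    the bottom axis chromosomal.
    """
    margin = 50
    plot_w = width - 2 * margin
    mid = height / 2
    max_bar = mid - 40

    values = []
    for h in cluster.hits:
        v = h.read.copy_number / h.read.genomic_hits if normalize \
            else float(h.read.copy_number)
        if log_scale:
            import math
            v = math.log10(1.0 + v)
        values.append(v)
    vmax = max(values) if values else 1.0
    span = max(cluster.span - 1, 1)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
        f'<line x1="{margin}" y1="{mid:.1f}" x2="{width - margin}" '
        f'y2="{mid:.1f}" stroke="black" stroke-width="1"/>',
    ]
    for h, v in zip(cluster.hits, values):
        x = margin + (h.start - cluster.start) / span * plot_w
        bar = max_bar * (v / vmax) if vmax > 0 else 0.0
        color = "red" if h.read.genomic_hits > 1 else "black"
        if h.strand == "+":
            y1, y2 = mid - bar, mid
        else:
            y1, y2 = mid, mid + bar
        parts.append(
            f'<line x1="{x:.2f}" y1="{y1:.2f}" x2="{x:.2f}" y2="{y2:.2f}" '
            f'stroke="{color}" stroke-width="1.5"/>'
        )
    # dual coordinate axes: cluster-relative (top), chromosomal (bottom)
    n_ticks = 5
    for t in range(n_ticks + 1):
        frac = t / n_ticks
        x = margin + frac * plot_w
        rel = round(frac * (cluster.span - 1))
        chrom_pos = cluster.start + rel
        parts.append(
            f'<text x="{x:.1f}" y="14" font-size="10" text-anchor="middle" '
            f'font-family="monospace">{rel}</text>'
        )
        parts.append(
            f'<text x="{x:.1f}" y="{height - 6}" font-size="10" '
            f'text-anchor="middle" font-family="monospace">{chrom_pos}</text>'
        )
    parts.append(
        f'<text x="{margin}" y="30" font-size="12" font-family="monospace">'
        f"{cluster.chromosome}:{cluster.start}-{cluster.end} "
        f"({cluster.directionality})</text>"
    )
    parts.append("</svg>")
    svg = "\n".join(parts) + "\n"
    if path is not None:
        Path(path).write_text(svg)
    return svg
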