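"""Gene models and genomic feature derivation.

Parses GFF3 annotations into per-gene models (longest transcript as the
representative isoform) and derives the six region classes over which
methylation is aggregated: promoter (a fixed window upstream of the TSS,
500 bp by default), 5'UTR, CDS, intron, 3'UTR and intergenic space.

All internal coordinates are 0-based half-open; GFF3 I/O converts at the
boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .errors import ParseError
from .config import FEATURE_KINDS, INTERGENIC

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """One gene with its representative (longest) transcript structure.

    All intervals are 0-based half-open and sorted by start. ``utr5`` and
    ``utr3`` are named by transcript orientation, not genomic position.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons."""
        out = []
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                out.append((e0, s1))
        return out

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1


def _validate_gff_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError as exc:
            raise ParseError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        if start > end or start < 1:
            raise ParseError(f"GFF3 line {lineno}: invalid interval {start}..{end}")
        if cols[6] not in {"+", "-", "."}:
            raise ParseError(f"GFF3 line {lineno}: invalid strand {cols[6]!r}")


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects.

    When a gene carries several mRNAs the longest one (summed exon length,
    ties broken by span then id) represents the gene.
    """
    text = Path(path).read_text()
    _validate_gff_lines(text)
    if not any(line and not line.startswith("#") for line in text.splitlines()):
        return []
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise ParseError(f"GFF3 parse failure in {path}: {exc}") from exc

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise ParseError(f"gene {gene.id} has no mRNA child")

        def _mrna_key(m):
            exons = list(db.children(m, featuretype="exon"))
            exon_len = sum(e.end - e.start + 1 for e in exons)
            return (exon_len, m.end - m.start + 1, m.id)

        rep = max(mrnas, key=_mrna_key)

        def _ivals(feature_type: str) -> list[Interval]:
            ivals = sorted(
                (f.start - 1, f.end) for f in db.children(rep, featuretype=feature_type)
            )
            return ivals

        exons = _ivals("exon")
        if not exons:
            raise ParseError(f"mRNA {rep.id} of gene {gene.id} has no exons")
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                cds=_ivals("CDS"),
                utr5=_ivals("five_prime_UTR"),
                utr3=_ivals("three_prime_UTR"),
            )
        )
    return models


def derive_features(
    models: list[GeneModel],
    chrom_lengths: dict[str, int],
    promoter_len: int = 500,
) -> pd.DataFrame:
    """Derive the feature regions used for methylation aggregation.

    Returns a BED-like frame with columns ``chrom, start, end, gene_id,
    feature_kind, strand`` (0-based half-open). Promoters are strand-aware
    windows upstream of the TSS, clipped at chromosome bounds. Intergenic
    space is the per-chromosome complement of gene spans and promoters; its
    ``gene_id`` is a stable region id ``IG_<chrom>_<k>``.
    """
    rows: list[tuple] = []
    for m in models:
        if m.chrom not in chrom_lengths:
            raise KeyError(f"no chromosome length for {m.chrom}")
        clen = chrom_lengths[m.chrom]
        if m.strand == "+":
            prom = (max(0, m.start - promoter_len), m.start)
        else:
            prom = (m.end, min(clen, m.end + promoter_len))
        if prom[1] > prom[0]:
            rows.append((m.chrom, *prom, m.gene_id, "promoter", m.strand))
        for kind, ivals in (
            ("utr5", m.utr5),
            ("cds", m.cds),
            ("intron", m.introns),
            ("utr3", m.utr3),
        ):
            for s, e in ivals:
                rows.append((m.chrom, s, e, m.gene_id, kind, m.strand))

    # intergenic: complement of gene spans union promoters
    by_chrom: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    for m in models:
        by_chrom[m.chrom].append((m.start, m.end))
    for chrom, s, e, gid, kind, strand in list(rows):
        if kind == "promoter":
            by_chrom[chrom].append((s, e))
    for chrom, clen in sorted(chrom_lengths.items()):
        merged = _merge_intervals(by_chrom.get(chrom, []))
        cursor, k = 0, 0
        for s, e in merged + [(clen, clen)]:
            if s > cursor:
                rows.append((chrom, cursor, min(s, clen), f"IG_{chrom}_{k}", INTERGENIC, "."))
                k += 1
            cursor = max(cursor, e)
            if cursor >= clen:
                break

    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "feature_kind", "strand"]
    )
    return df.sort_values(["chrom", "start", "end", "gene_id"], kind="stable").reset_index(
        drop=True
    )


def _merge_intervals(ivals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def assign_sites(features: pd.DataFrame, positions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Map 0-based site positions to every feature interval containing them.

    A site may map to several features (e.g. the promoter of one gene
    overlapping the 3'UTR of its neighbour); every assignment is retained.
    Sites covered by no feature interval are not listed (intergenic space is
    itself a set of feature intervals, so a site outside all of them does not
    occur for complete annotations).

    Returns a frame with columns ``chrom, pos, gene_id, feature_kind``.
    """
    frames = []
    for chrom, pos in positions.items():
        pos = np.asarray(pos)
        if pos.size == 0:
            continue
        order = np.argsort(pos, kind="stable")
        sorted_pos = pos[order]
        sub = features[features["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        lo = np.searchsorted(sorted_pos, starts, side="left")
        hi = np.searchsorted(sorted_pos, ends, side="left")
        n_hits = hi - lo
        keep = n_hits > 0
        if not keep.any():
            continue
        idx = np.concatenate([np.arange(l, h) for l, h in zip(lo[keep], hi[keep])])
        rep = np.repeat(np.flatnonzero(keep), n_hits[keep])
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sorted_pos[idx],
                    "gene_id": sub["gene_id"].to_numpy()[rep],
                    "feature_kind": sub["feature_kind"].to_numpy()[rep],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "gene_id", "feature_kind"])
    return pd.concat(frames, ignore_index=True)


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})


def write_gff3(models: list[GeneModel], chrom_lengths: dict[str, int], path: str | Path) -> None:
    """Serialize gene models as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for chrom, clen in sorted(chrom_lengths.items()):
        lines.append(f"##sequence-region {chrom} 1 {clen}")
    for m in sorted(models, key=lambda m: (m.chrom, m.start)):
        gid, mid = m.gene_id, f"{m.gene_id}.1"

        def _line(ftype, s, e, parent):
            return (
                f"{m.chrom}\tdivergescan\t{ftype}\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{parent}"
            )

        lines.append(_line("gene", m.start, m.end, f"ID={gid}"))
        lines.append(_line("mRNA", m.start, m.end, f"ID={mid};Parent={gid}"))
        for ftype, ivals in (
            ("exon", m.exons),
            ("five_prime_UTR", m.utr5),
            ("CDS", m.cds),
            ("three_prime_UTR", m.utr3),
        ):
            for s, e in ivals:
                lines.append(_line(ftype, s, e, f"Parent={mid}"))
    Path(path).write_text("\n".join(lines) + "\n")
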