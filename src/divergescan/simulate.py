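"""Seeded synthetic genomes, methylomes, count matrices and CDS pairs.

Every generator draws from a named sub-stream of the global seed (see
:mod:`divergescan.config`), so the same :class:`SimulationConfig` always
yields byte-identical outputs, and each component can be regenerated on its
own. Truth tables record every planted effect; genes and features not listed
carry no planted effect.

The methylation noise model is deliberately simple: a site's true level in a
given replicate is the feature baseline for its context, plus the planted
difference when the site lies in a differentially methylated feature of the
hypermethylated genotype, plus independent Gaussian jitter per site per
sample, clamped to [0, 1]. Coverage is negative-binomial per site per sample
and the methylated read count is binomial at the true level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    CONTEXTS,
    FEATURE_KINDS,
    GENOTYPES,
    STAGES_EXPR,
    STAGES_METH,
    SimulationConfig,
    expression_design,
    methylome_design,
)
from .errors import ConfigurationError, MissingDataError
from .features import GeneModel, derive_features, write_gff3
from . import kaks as _kaks

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MIN_EXON = 60
_MAX_INTRON = 200


@dataclass
class SimulatedGenomes:
    """Gene models, chromosome sequences and the ortholog map for both genotypes."""

    models: dict[str, list[GeneModel]]
    chrom_lengths: dict[str, dict[str, int]]
    sequences: dict[str, dict[str, np.ndarray]]  # arrays of single characters
    ortholog_map: pd.DataFrame  # columns: pair_id, HAL2, FIL2


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _map_transcript_interval(
    exons: list[tuple[int, int]], strand: str, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Project a transcript-coordinate interval onto genomic exon intervals."""
    ordered = exons if strand == "+" else list(reversed(exons))
    out, offset = [], 0
    for s, e in ordered:
        length = e - s
        a, b = max(t_start, offset), min(t_end, offset + length)
        if b > a:
            if strand == "+":
                out.append((s + (a - offset), s + (b - offset)))
            else:
                out.append((e - (b - offset), e - (a - offset)))
        offset += length
    return sorted(out)


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int,
                config: SimulationConfig) -> GeneModel:
    lo, hi = config.gene_length_range
    elo, ehi = config.exons_per_gene_range
    length = int(rng.integers(lo, hi + 1))
    max_k = max(elo, min(ehi, (length - _MIN_EXON) // (_MIN_EXON + _MAX_INTRON) + 1))
    k = int(rng.integers(elo, max_k + 1))
    intron_lens = rng.integers(_MIN_EXON, _MAX_INTRON + 1, size=k - 1) if k > 1 else np.array([], int)
    exon_total = length - int(intron_lens.sum())
    if exon_total < k * _MIN_EXON:
        raise ConfigurationError(
            f"gene_length_range {config.gene_length_range} too short for "
            f"{k} exons of >= {_MIN_EXON} bp"
        )
    extra = rng.multinomial(exon_total - k * _MIN_EXON, np.full(k, 1.0 / k))
    exon_lens = extra + _MIN_EXON
    strand = "+" if rng.random() < 0.5 else "-"

    exons, cursor = [], start
    for i in range(k):
        exons.append((cursor, cursor + int(exon_lens[i])))
        cursor += int(exon_lens[i])
        if i < k - 1:
            cursor += int(intron_lens[i])
    end = cursor

    transcript_len = int(exon_lens.sum())
    u5 = max(0, int(round(0.15 * transcript_len)))
    u3 = max(0, int(round(0.15 * transcript_len)))
    cds_len = transcript_len - u5 - u3
    u3 += cds_len % 3
    cds_len -= cds_len % 3
    if cds_len < 3:
        u5, u3, cds_len = 0, transcript_len - 3, 3

    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        exons=exons,
        cds=_map_transcript_interval(exons, strand, u5, u5 + cds_len),
        utr5=_map_transcript_interval(exons, strand, 0, u5),
        utr3=_map_transcript_interval(exons, strand, u5 + cds_len, transcript_len),
    )


def generate_gene_models(config: SimulationConfig) -> SimulatedGenomes:
    """Generate annotation sets for both genotypes plus the ortholog map.

    Genes are laid out left to right with intergenic gaps wider than the
    promoter window, round-robin across chromosomes, so neither gene spans nor
    promoters overlap. The two genotype genomes share gene order and ids up to
    the genotype prefix; the ortholog map is the resulting bijection.
    """
    n_digits = max(4, len(str(config.n_genes)))
    pair_ids = [f"og{i + 1:0{n_digits}d}" for i in range(config.n_genes)]
    models: dict[str, list[GeneModel]] = {}
    chrom_lengths: dict[str, dict[str, int]] = {}
    sequences: dict[str, dict[str, np.ndarray]] = {}

    for genotype in GENOTYPES:
        rng = config.rng(f"genome_{genotype}")
        geno_models: list[GeneModel] = []
        cursors = {f"chr{c + 1}": 0 for c in range(config.n_chromosomes)}
        for i, pair in enumerate(pair_ids):
            chrom = f"chr{(i % config.n_chromosomes) + 1}"
            gap = int(rng.integers(*config.intergenic_gap_range))
            start = cursors[chrom] + gap
            gene = _build_gene(rng, f"{genotype}_{pair[2:]}", chrom, start, config)
            geno_models.append(gene)
            cursors[chrom] = gene.end
        lengths = {
            chrom: cursor + int(rng.integers(*config.intergenic_gap_range))
            for chrom, cursor in cursors.items()
        }
        models[genotype] = geno_models
        chrom_lengths[genotype] = lengths
        sequences[genotype] = {
            chrom: _BASES[rng.integers(0, 4, size=length)]
            for chrom, length in sorted(lengths.items())
        }

    ortholog_map = pd.DataFrame(
        {
            "pair_id": pair_ids,
            GENOTYPES[0]: [m.gene_id for m in models[GENOTYPES[0]]],
            GENOTYPES[1]: [m.gene_id for m in models[GENOTYPES[1]]],
        }
    )
    return SimulatedGenomes(models, chrom_lengths, sequences, ortholog_map)


# ---------------------------------------------------------------------------
# cytosine maps
# ---------------------------------------------------------------------------

def cytosine_map(seq: np.ndarray, chrom: str) -> pd.DataFrame:
    """All cytosines of a chromosome on both strands with context calls.

    Positions are 0-based; sites within 2 bp of either chromosome end are
    skipped so every site has a full trinucleotide.
    """
    n = len(seq)
    frames = []
    idx = np.flatnonzero(seq == "C")
    idx = idx[(idx >= 2) & (idx < n - 2)]
    if idx.size:
        b1, b2 = seq[idx + 1], seq[idx + 2]
        context = np.where(b1 == "G", "CG", np.where(b2 == "G", "CHG", "CHH"))
        tri = np.char.add(np.char.add(seq[idx], b1), b2)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": idx, "strand": "+", "context": context, "tri": tri}
        ))
    idx = np.flatnonzero(seq == "G")
    idx = idx[(idx >= 2) & (idx < n - 2)]
    if idx.size:
        b1 = np.vectorize(_COMP.get)(seq[idx - 1])
        b2 = np.vectorize(_COMP.get)(seq[idx - 2])
        context = np.where(b1 == "G", "CG", np.where(b2 == "G", "CHG", "CHH"))
        tri = np.char.add(np.char.add("C", b1), b2)
        frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": idx, "strand": "-", "context": context, "tri": tri}
        ))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "context", "tri"]
    )
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """Negative-binomial draw parameterized by mean and dispersion alpha.

    Var = mean + alpha * mean^2; implemented as a gamma-Poisson mixture.
    """
    mean = np.broadcast_to(np.asarray(mean, float), size)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------

def simulate_methylomes(
    genomes: SimulatedGenomes,
    config: SimulationConfig,
    outdir: str | Path,
) -> tuple[dict[str, Path], pd.DataFrame, pd.DataFrame]:
    """Write per-sample CX cytosine reports and return the DMR truth table.

    Returns ``(report_paths, dmr_truth, features)`` where ``dmr_truth`` has
    one row per planted feature contrast: pair id, feature kind, context,
    planted delta (FIL2 - HAL2 sign convention) and the hypermethylated
    genotype.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = config.rng("methylome")
    baseline = dict(zip(CONTEXTS, config.baseline_meth))

    # plant DMRs on ortholog-pair features (one context per selected feature)
    n_pairs = len(genomes.ortholog_map)
    combos = [(p, k) for p in range(n_pairs) for k in FEATURE_KINDS]
    n_planted = int(round(config.frac_dmr_features * len(combos)))
    chosen = rng.choice(len(combos), size=n_planted, replace=False) if n_planted else []
    truth_rows = []
    for ci in sorted(chosen):
        pair_idx, kind = combos[ci]
        context = CONTEXTS[int(rng.integers(0, len(CONTEXTS)))]
        hyper = GENOTYPES[int(rng.integers(0, 2))]
        pair = genomes.ortholog_map.iloc[pair_idx]
        delta = config.dmr_delta if hyper == GENOTYPES[1] else -config.dmr_delta
        truth_rows.append(
            {
                "pair_id": pair["pair_id"],
                "feature_kind": kind,
                "context": context,
                "delta": delta,
                "hyper_genotype": hyper,
            }
        )
    dmr_truth = pd.DataFrame(
        truth_rows, columns=["pair_id", "feature_kind", "context", "delta", "hyper_genotype"]
    )

    design = methylome_design(config)
    paths: dict[str, Path] = {}
    feature_frames = []
    for genotype in GENOTYPES:
        features = derive_features(
            genomes.models[genotype],
            genomes.chrom_lengths[genotype],
            promoter_len=config.promoter_len,
        )
        feature_frames.append(features.assign(genotype=genotype))
        sites = pd.concat(
            [cytosine_map(seq, chrom) for chrom, seq in sorted(genomes.sequences[genotype].items())],
            ignore_index=True,
        )
        base_level = sites["context"].map(baseline).to_numpy(float)

        # apply planted deltas to this genotype's copies of the chosen features
        delta_by_site = np.zeros(len(sites))
        if len(dmr_truth):
            gmap = genomes.ortholog_map.set_index("pair_id")[genotype]
            planted = dmr_truth.assign(gene_id=dmr_truth["pair_id"].map(gmap))
            planted = planted[planted["hyper_genotype"] == genotype]
            from .features import assign_sites

            positions = {c: g["pos"].to_numpy() for c, g in sites.groupby("chrom")}
            assignment = assign_sites(features, positions)
            hits = assignment.merge(planted, on=["gene_id", "feature_kind"], how="inner")
            if len(hits):
                site_key = sites.set_index(["chrom", "pos", "context"]).index
                lookup = pd.MultiIndex.from_frame(hits[["chrom", "pos", "context"]])
                mask = site_key.isin(lookup)
                # each strand copy of a planted cytosine shifts by the same delta
                delta_by_site[mask] = config.dmr_delta

        true_base = np.clip(base_level + delta_by_site, 0.0, 1.0)
        for _, row in design[design["genotype"] == genotype].iterrows():
            level = np.clip(
                true_base + rng.normal(0.0, config.site_noise_sd, size=len(sites)), 0.0, 1.0
            )
            coverage = _nb_counts(rng, config.coverage_mean, config.coverage_dispersion, len(sites))
            meth = rng.binomial(coverage, level)
            report = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"] + 1,  # CX reports are 1-based
                    "strand": sites["strand"],
                    "count_methylated": meth,
                    "count_unmethylated": coverage - meth,
                    "context": sites["context"],
                    "trinucleotide": sites["tri"],
                }
            )
            path = outdir / f"{row['sample']}.CX_report.txt"
            report.to_csv(path, sep="\t", index=False, header=False)
            paths[row["sample"]] = path

    features_all = pd.concat(feature_frames, ignore_index=True)
    return paths, dmr_truth, features_all


def simulate_chloroplast(config: SimulationConfig) -> pd.DataFrame:
    """CX-format report for an unmethylated chloroplast control.

    True methylation is zero everywhere; observed methylated counts arise only
    from bisulfite conversion failure.
    """
    rng = config.rng("chloroplast")
    n = config.chloroplast_n_sites
    coverage = _nb_counts(rng, config.chloroplast_coverage_mean, config.coverage_dispersion, n)
    meth = rng.binomial(coverage, config.conversion_failure_rate)
    context = rng.choice(CONTEXTS, size=n, p=[0.25, 0.25, 0.5])
    tri = np.where(context == "CG", "CGA", np.where(context == "CHG", "CAG", "CAA"))
    return pd.DataFrame(
        {
            "chrom": "chrC",
            "pos": np.arange(1, n + 1) * 3,
            "strand": rng.choice(["+", "-"], size=n),
            "count_methylated": meth,
            "count_unmethylated": coverage - meth,
            "context": context,
            "trinucleotide": tri,
        }
    )


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_counts(
    genomes: SimulatedGenomes, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the factorial RNA-seq count matrix with planted effects.

    Returns ``(counts, design, deg_truth)``. Counts are indexed by ortholog
    pair id with one column per sample. Planted effects are mutually
    exclusive per gene:

    - ``genotype``: a constant FIL2-vs-HAL2 log2 fold change at every stage;
    - ``development``: a common expression trend over stages, identical in
      both genotypes (no genotype difference);
    - ``interaction``: a heterochronic rank change — the FIL2-vs-HAL2 log2
      fold change flips sign at a random changepoint along the stage series.

    ``deg_truth`` records the per-stage FIL2 - HAL2 log2FC (``lfc_D*``) and
    the shared stage trend (``trend_D*``) for every non-null gene.
    """
    rng = config.rng("counts")
    design = expression_design(config)
    pair_ids = genomes.ortholog_map["pair_id"].tolist()
    n = len(pair_ids)

    f_g, f_d, f_i = config.frac_deg
    if f_g + f_d + f_i > 1:
        raise ConfigurationError("frac_deg proportions sum to more than 1")
    perm = rng.permutation(n)
    n_g, n_d, n_i = (int(round(f * n)) for f in (f_g, f_d, f_i))
    effect = np.array(["none"] * n, dtype=object)
    effect[perm[:n_g]] = "genotype"
    effect[perm[n_g:n_g + n_d]] = "development"
    effect[perm[n_g + n_d:n_g + n_d + n_i]] = "interaction"

    base = np.exp(rng.normal(np.log(200.0), 1.0, size=n))
    lfc = np.zeros((n, len(STAGES_EXPR)))       # FIL2 - HAL2, log2
    trend = np.zeros((n, len(STAGES_EXPR)))     # shared development trend, log2
    signs = rng.choice([-1.0, 1.0], size=n)
    for i in range(n):
        if effect[i] == "genotype":
            lfc[i, :] = signs[i] * config.deg_log2fc
        elif effect[i] == "development":
            trend[i, :] = signs[i] * config.deg_log2fc * np.linspace(0, 1, len(STAGES_EXPR))
        elif effect[i] == "interaction":
            # heterochronic rank change: the direction of the genotype
            # difference flips at a random changepoint along the series
            cp = int(rng.integers(1, len(STAGES_EXPR)))
            lfc[i, :cp] = -signs[i] * config.deg_log2fc
            lfc[i, cp:] = signs[i] * config.deg_log2fc

    lib_sizes = rng.uniform(*config.library_size_range, size=len(design))
    size_factor = lib_sizes / lib_sizes.mean()
    counts = np.empty((n, len(design)), dtype=np.int64)
    for j, row in design.iterrows():
        s = STAGES_EXPR.index(row["stage"])
        geno_shift = lfc[:, s] if row["genotype"] == GENOTYPES[1] else 0.0
        mu = base * size_factor[j] * 2.0 ** (trend[:, s] + geno_shift)
        counts[:, j] = _nb_counts(rng, mu, config.nb_dispersion, n)

    counts_df = pd.DataFrame(counts, index=pd.Index(pair_ids, name="gene_id"),
                             columns=design["sample"])
    truth_rows = []
    for i in range(n):
        if effect[i] == "none":
            continue
        rec = {"gene_id": pair_ids[i], "effect": effect[i]}
        rec.update({f"lfc_{st}": lfc[i, s] for s, st in enumerate(STAGES_EXPR)})
        rec.update({f"trend_{st}": trend[i, s] for s, st in enumerate(STAGES_EXPR)})
        truth_rows.append(rec)
    deg_truth = pd.DataFrame(truth_rows)
    return counts_df, design, deg_truth


# ---------------------------------------------------------------------------
# CDS pairs
# ---------------------------------------------------------------------------

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _single_step_neighbors(codon: str):
    for pos in range(3):
        for nt in "ACGT":
            if nt != codon[pos]:
                yield pos, codon[:pos] + nt + codon[pos + 1:]


def mutate_codon_pair(
    rng: np.random.Generator, codons: list[str], n_syn: int, n_nonsyn: int
) -> tuple[list[str], int, int]:
    """Apply single-nucleotide substitutions at distinct codons.

    Synonymous substitutions preserve the encoded amino acid; non-synonymous
    ones change it without creating a stop codon. Returns the mutated codon
    list and the realized (synonymous, non-synonymous) counts.
    """
    if n_syn + n_nonsyn > len(codons):
        raise ConfigurationError(
            f"requested {n_syn + n_nonsyn} substitutions over {len(codons)} codons"
        )
    mutated = list(codons)
    available = list(range(len(codons)))
    realized_s = realized_n = 0
    for want_syn, want in ((True, n_syn), (False, n_nonsyn)):
        done = 0
        rng.shuffle(available)
        still = []
        for idx in available:
            if done >= want:
                still.append(idx)
                continue
            codon = mutated[idx]
            aa = _kaks.translate_codon(codon)
            options = [
                alt
                for _, alt in _single_step_neighbors(codon)
                if _kaks.translate_codon(alt) != "*"
                and (_kaks.translate_codon(alt) == aa) == want_syn
            ]
            if not options:
                still.append(idx)
                continue
            mutated[idx] = options[int(rng.integers(0, len(options)))]
            done += 1
        if want_syn:
            realized_s = done
        else:
            realized_n = done
        available = still
    return mutated, realized_s, realized_n


def simulate_cds_pairs(config: SimulationConfig) -> tuple[dict[str, tuple[str, str]], pd.DataFrame]:
    """Aligned CDS pairs with controlled substitution counts.

    A fraction ``frac_kaks_positive`` of pairs receives an excess of
    non-synonymous substitutions calibrated (via the ancestor's NG86 site
    counts) to land above omega = 1; the remainder are purifying. Returns the
    pair sequences and a truth table with realized substitution counts.
    """
    rng = config.rng("cds")
    n_digits = max(4, len(str(config.n_genes)))
    n_pairs = min(config.n_cds_pairs, config.n_genes) if config.n_genes else config.n_cds_pairs
    pairs: dict[str, tuple[str, str]] = {}
    rows = []
    for i in range(n_pairs):
        pair_id = f"og{i + 1:0{n_digits}d}"
        n_codons = int(rng.integers(*config.cds_n_codons_range))
        codons = [
            _SENSE_CODONS[int(k)] for k in rng.integers(0, len(_SENSE_CODONS), size=n_codons)
        ]
        positive = rng.random() < config.frac_kaks_positive
        n_syn = int(rng.integers(2, 6))
        s_sites, n_sites = _kaks.count_sites("".join(codons))
        omega_target = rng.uniform(1.6, 2.4) if positive else rng.uniform(0.25, 0.55)
        n_nonsyn = max(1, int(round(omega_target * n_syn * n_sites / s_sites)))
        mutated, rs, rn = mutate_codon_pair(rng, codons, n_syn, n_nonsyn)
        pairs[pair_id] = ("".join(codons), "".join(mutated))
        rows.append(
            {
                "pair_id": pair_id,
                "n_codons": n_codons,
                "planted_synonymous": rs,
                "planted_nonsynonymous": rn,
                "planted_positive": positive,
            }
        )
    return pairs, pd.DataFrame(rows)


def write_cds_pairs(pairs: dict[str, tuple[str, str]], path: str | Path) -> None:
    """Write pairs as FASTA with two records per pair (suffixes _A and _B)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for pair_id, (a, b) in pairs.items():
        records.append(SeqRecord(Seq(a), id=f"{pair_id}_A", description=""))
        records.append(SeqRecord(Seq(b), id=f"{pair_id}_B", description=""))
    SeqIO.write(records, str(path), "fasta")


def read_cds_pairs(path: str | Path) -> dict[str, tuple[str, str]]:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    pairs = {}
    for name, seq in seqs.items():
        if name.endswith("_A"):
            pair_id = name[:-2]
            if f"{pair_id}_B" not in seqs:
                raise MissingDataError(f"pair {pair_id} lacks a _B record")
            pairs[pair_id] = (seq, seqs[f"{pair_id}_B"])
    return pairs


# ---------------------------------------------------------------------------
# feature-level generator (no genome plumbing)
# ---------------------------------------------------------------------------

def simulate_feature_table(
    n_features: int,
    n_sites: int = 10,
    n_replicates: int = 3,
    baseline: float = 0.66,
    site_noise_sd: float = 0.05,
    coverage_mean: float = 20.0,
    coverage_dispersion: float = 0.3,
    frac_planted: float = 0.0,
    delta: float = 0.3,
    seed: int = 0,
    context: str = "CG",
    feature_kind: str = "promoter",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature-level view of the methylome model, for calibration studies.

    Simulates replicate feature methylation levels directly — each feature has
    ``n_sites`` cytosines whose true levels are baseline plus per-site
    per-replicate Gaussian jitter (plus ``delta`` in group B for planted
    features), observed through negative-binomial coverage and binomial read
    sampling; the reported level is the unweighted mean of site proportions.

    Returns a long table with columns ``gene_id, feature_kind, context,
    sample, group, mean_level, n_sites`` and a truth table of planted
    features. Group labels follow the genotype convention (A = HAL2,
    B = FIL2); planted features are hypermethylated in group B.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_planted = int(round(frac_planted * n_features))
    planted = np.zeros(n_features, bool)
    planted[rng.choice(n_features, size=n_planted, replace=False)] = True

    rows = []
    for group, group_label in (("A", "HAL2"), ("B", "FIL2")):
        shift = np.where(planted & (group == "B"), delta, 0.0)
        for rep in range(n_replicates):
            level = np.clip(
                baseline
                + shift[:, None]
                + rng.normal(0.0, site_noise_sd, size=(n_features, n_sites)),
                0.0,
                1.0,
            )
            coverage = _nb_counts(rng, coverage_mean, coverage_dispersion, (n_features, n_sites))
            meth = rng.binomial(coverage, level)
            with np.errstate(invalid="ignore"):
                prop = np.where(coverage > 0, meth / np.maximum(coverage, 1), np.nan)
            mean_level = np.nanmean(prop, axis=1)
            n_used = (coverage > 0).sum(axis=1)
            for i in range(n_features):
                rows.append(
                    {
                        "gene_id": f"f{i + 1:05d}",
                        "feature_kind": feature_kind,
                        "context": context,
                        "sample": f"{group_label}_r{rep + 1}",
                        "group": group_label,
                        "mean_level": mean_level[i],
                        "n_sites": int(n_used[i]),
                    }
                )
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "gene_id": [f"f{i + 1:05d}" for i in np.flatnonzero(planted)],
            "feature_kind": feature_kind,
            "context": context,
            "delta": delta,
            "hyper_genotype": "FIL2",
        }
    )
    return table, truth


def simulate_profile_clusters(
    n_profiles: int = 400,
    n_clusters: int = 4,
    dim: int = 8,
    separation: float = 6.0,
    within_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted Gaussian profile mixture for clustering validation.

    Cluster centers are scaled so their minimum pairwise distance equals
    ``separation`` times the within-cluster standard deviation. Returns
    ``(profiles, labels)``.
    """
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, 1.0, (n_clusters, dim))
    centers *= separation * within_sd / pdist(centers).min()
    labels = rng.integers(0, n_clusters, size=n_profiles)
    profiles = centers[labels] + rng.normal(0.0, within_sd, (n_profiles, dim))
    return profiles, labels


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic study into ``outdir``.

    Writes GFF3 annotations, the ortholog map, per-sample CX reports, the
    chloroplast control, the count matrix with its design table, CDS pair
    FASTA, and all truth tables. Returns a manifest of paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    genomes = generate_gene_models(config)
    for genotype in GENOTYPES:
        p = outdir / f"{genotype}.gff3"
        write_gff3(genomes.models[genotype], genomes.chrom_lengths[genotype], p)
        manifest[f"gff_{genotype}"] = p
    p = outdir / "orthologs.tsv"
    genomes.ortholog_map.to_csv(p, sep="\t", index=False)
    manifest["orthologs"] = p

    meth_dir = outdir / "methylomes"
    report_paths, dmr_truth, features = simulate_methylomes(genomes, config, meth_dir)
    for sample, path in report_paths.items():
        manifest[f"cx_{sample}"] = path
    p = outdir / "dmr_truth.tsv"
    dmr_truth.to_csv(p, sep="\t", index=False)
    manifest["dmr_truth"] = p
    p = outdir / "features.tsv"
    features.to_csv(p, sep="\t", index=False)
    manifest["features"] = p

    chloro = simulate_chloroplast(config)
    p = outdir / "chloroplast.CX_report.txt"
    chloro.to_csv(p, sep="\t", index=False, header=False)
    manifest["chloroplast"] = p

    counts, design, deg_truth = simulate_counts(genomes, config)
    p = outdir / "counts.tsv"
    counts.to_csv(p, sep="\t")
    manifest["counts"] = p
    p = outdir / "design_expr.tsv"
    design.to_csv(p, sep="\t", index=False)
    manifest["design_expr"] = p
    p = outdir / "design_meth.tsv"
    methylome_design(config).to_csv(p, sep="\t", index=False)
    manifest["design_meth"] = p
    p = outdir / "deg_truth.tsv"
    deg_truth.to_csv(p, sep="\t", index=False)
    manifest["deg_truth"] = p

    pairs, kaks_truth = simulate_cds_pairs(config)
    p = outdir / "cds_pairs.fasta"
    write_cds_pairs(pairs, p)
    manifest["cds_pairs"] = p
    p = outdir / "kaks_truth.tsv"
    kaks_truth.to_csv(p, sep="\t", index=False)
    manifest["kaks_truth"] = p
    return manifest
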