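"""Self-contained synthetic cohorts with known ground truth.

Everything the pipeline consumes can be generated here: a toy genome and
GTF with constructed uORFs and 3'UTR junctions (including 40/50/60 nt
boundary cases around the EJC distance rule), NB-distributed transcript
counts in which NMD-target transcripts are attenuated by a per-sample
efficiency factor eta (target mean = control mean * exp(-eta)), allele
counts in which the mutant allele is attenuated the same way, multi-tissue
cohorts with additive tissue shifts, and GISTIC-style copy-number matrices
with planted segments whose carriers receive an eta decrement.  A manifest
records every true eta, pairing, class label, planted segment and seed, so
expected estimates are computable analytically.

Randomness derives from one global seed fanned out to per-component child
streams through a fixed registry (`_COMPONENT_KEYS`), so adding a component
never perturbs existing streams.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

_COMPONENT_KEYS = {
    "annotation": 1,
    "etg": 2,
    "ase": 3,
    "cna": 4,
    "cohort": 5,
}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Child generator for one named component of the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_COMPONENT_KEYS[component],))
    )


def _nb_draw(rng, mean, theta, size=None):
    """NB(mean, theta) with variance mean + mean^2/theta."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=size)


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Per-sample true efficiency: eta = base_eta + tissue delta + N(0,
    individual_effect_sd).  ``depth`` is the mean reads per transcript or
    locus; ``theta`` the NB dispersion (variance mean + mean^2/theta);
    ``library_size_sd`` the log-normal sd of a per-sample multiplicative
    depth factor (0 disables it).
    """

    n_individuals: int = 100
    tissues: list[tuple[str, int, float]] | None = None  # (name, n_samples, delta)
    base_eta: float = 1.0
    individual_effect_sd: float = 0.0
    theta: float = 10.0
    depth: float = 100.0
    library_size_sd: float = 0.0
    seed: int = 0

    def sample_frame(self) -> pd.DataFrame:
        rng = component_rng(self.seed, "cohort")
        rows = []
        if self.tissues:
            for name, n, delta in self.tissues:
                for i in range(n):
                    rows.append({"sample_id": f"{name}_{i:04d}", "tissue": name, "delta": delta})
        else:
            for i in range(self.n_individuals):
                rows.append({"sample_id": f"S{i:04d}", "tissue": "cohort", "delta": 0.0})
        df = pd.DataFrame(rows)
        df["individual_effect"] = rng.normal(0.0, self.individual_effect_sd, len(df))
        df["eta"] = self.base_eta + df["delta"] + df["individual_effect"]
        df["library_factor"] = (
            rng.lognormal(0.0, self.library_size_sd, len(df))
            if self.library_size_sd > 0
            else 1.0
        )
        return df.set_index("sample_id")


@dataclass
class GroundTruthManifest:
    """Everything needed to compute expected estimates analytically."""

    eta: dict = field(default_factory=dict)  # sample -> true eta
    seeds: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)
    variant_truth: pd.DataFrame | None = None
    planted_segments: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# toy annotation
# ---------------------------------------------------------------------------

_SAFE_CODONS = [  # no stop codons; used for random CDS filler
    "GCT", "GCC", "TGC", "GAC", "GAA", "TTC", "GGT", "CAC", "CTG",
    "AAG", "ATG", "AAC", "CCG", "CAG", "CGT", "TCC", "ACC", "GTG", "TGG",
]
_NO_A = "CGT"  # 5'UTR background alphabet: no A, hence no spurious ATG
_AFREE_CODONS = ["TGC", "TTC", "GGT", "CTG", "TCC", "GTG", "TGG", "GGC", "CCG"]


def _rand_seq(rng, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _uorf(rng, n_codons: int = 8) -> str:
    # A-free body: no internal ATG, no internal stop, exactly one uORF per insert
    body = "".join(rng.choice(_AFREE_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


@dataclass
class AnnotationBundle:
    gtf_path: str
    fasta_path: str
    truth: pd.DataFrame
    genome: dict


def generate_annotation(
    n_genes: int,
    feature_mix: dict[str, float] | None = None,
    seed: int = 0,
    out_dir: str = ".",
    include_boundary_cases: bool = True,
    chrom: str = "chrS",
) -> AnnotationBundle:
    """Write a toy GTF + FASTA with per-transcript truth labels.

    ``feature_mix`` gives the fraction of genes whose target transcript
    carries a 3'UTR EJC (``ejc``), two qualifying uORFs (``uorf``) or neither
    (``none``); fractions must sum to <= 1 (remainder goes to ``none``).
    Each gene gets a target transcript (with the assigned feature) and a
    featureless control transcript, on alternating strands.  With
    ``include_boundary_cases`` three extra genes place the 3'UTR junction at
    40, 50 and 60 nt past the stop codon (only 60 triggers under the strict
    > 50 nt rule).
    """
    mix = dict(feature_mix or {"ejc": 0.5, "uorf": 0.3, "none": 0.2})
    total = sum(mix.values())
    if total > 1 + 1e-9:
        raise ValueError("feature_mix fractions exceed 1")
    mix.setdefault("none", 0.0)
    mix["none"] += 1 - total

    rng = component_rng(seed, "annotation")
    n_ejc = int(round(mix.get("ejc", 0) * n_genes))
    n_uorf = int(round(mix.get("uorf", 0) * n_genes))
    assignments = ["ejc"] * n_ejc + ["uorf"] * n_uorf
    assignments += ["none"] * (n_genes - len(assignments))

    genes = [(f"G{i:04d}", assignments[i], 60) for i in range(n_genes)]
    if include_boundary_cases:
        for j, d in enumerate((40, 50, 60)):
            genes.append((f"GB{j:02d}", "ejc", d))

    genome_parts: list[str] = []
    gtf_lines: list[str] = []
    truth_rows: list[dict] = []
    cursor = 0

    for gi, (gene_id, feature, ejc_dist) in enumerate(genes):
        strand = "+" if gi % 2 == 0 else "-"
        for role in ("target", "control"):
            tid = f"{gene_id}.{'t1' if role == 'target' else 't2'}"
            # --- build the spliced sequence, 5'->3'
            if role == "target" and feature == "uorf":
                utr5 = (
                    _rand_seq(rng, _NO_A, 6) + _uorf(rng) + _rand_seq(rng, _NO_A, 6)
                    + _uorf(rng) + _rand_seq(rng, _NO_A, 6)
                )
            else:
                utr5 = _rand_seq(rng, _NO_A, 60)
            n_codons = int(rng.integers(50, 70))
            cds = "ATG" + "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons)) + "TAA"
            utr3 = _rand_seq(rng, "ACGT", 150)
            seq = utr5 + cds + utr3
            cds_start, cds_end = len(utr5), len(utr5) + len(cds)

            junctions = [cds_start + 3 * (n_codons // 2)]  # one junction mid-CDS
            if role == "target" and feature == "ejc":
                junctions.append(cds_end + ejc_dist)
            junctions = sorted(set(junctions))

            # --- exon segments with introns, laid on the genome
            bounds = [0] + junctions + [len(seq)]
            exon_seqs = [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
            intron = lambda: _rand_seq(rng, "ACGT", 60)  # noqa: E731
            locus, offsets = "", []
            for k, es in enumerate(exon_seqs):
                if k:
                    locus += intron()
                offsets.append(len(locus))
                locus += es
            gpiece = locus if strand == "+" else str(Seq(locus).reverse_complement())
            gstart = cursor
            genome_parts.append(gpiece)
            genome_parts.append("N" * 100)
            cursor += len(gpiece) + 100
            L = len(locus)

            def to_genomic(a, b, off, elen):
                """Map tx-span [a, b) inside an exon to a genomic interval."""
                if strand == "+":
                    return gstart + off + a, gstart + off + b
                return gstart + L - off - b, gstart + L - off - a

            exon_ivs, cds_ivs = [], []
            for off, (a, b), es in zip(offsets, zip(bounds[:-1], bounds[1:]), exon_seqs):
                exon_ivs.append(to_genomic(0, len(es), off, len(es)))
                lo, hi = max(a, cds_start), min(b, cds_end)
                if lo < hi:
                    cds_ivs.append(to_genomic(lo - a, hi - a, off, len(es)))

            for ftype, ivs in (("exon", exon_ivs), ("CDS", cds_ivs)):
                for s, e in sorted(ivs):
                    gtf_lines.append(
                        f"{chrom}\tsynthetic\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                        f'gene_id "{gene_id}"; transcript_id "{tid}"; '
                        f'transcript_biotype "protein_coding";'
                    )

            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": tid,
                    "role": role,
                    "strand": strand,
                    "feature": feature if role == "target" else "none",
                    "ejc_distance_nt": ejc_dist if role == "target" and feature == "ejc" else np.nan,
                    "expect_3utr_ejc": role == "target" and feature == "ejc" and ejc_dist > 50,
                    "expect_n_uorfs": 2 if role == "target" and feature == "uorf" else 0,
                }
            )

    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "genome.fa")
    gtf_path = os.path.join(out_dir, "annotation.gtf")
    genome_seq = "".join(genome_parts)
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 80):
            fh.write(genome_seq[i : i + 80] + "\n")
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return AnnotationBundle(gtf_path, fasta_path, truth, {chrom: genome_seq})


# ---------------------------------------------------------------------------
# ETG counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEtg:
    counts: pd.DataFrame  # transcripts x samples
    pairs: pd.DataFrame  # gene_id, target_id, control_id
    transcript_lengths: pd.Series
    samples: pd.DataFrame  # sample frame with true eta
    manifest: GroundTruthManifest


def simulate_etg_counts(
    spec: CohortSpec, n_pairs: int = 50, samples: pd.DataFrame | None = None
) -> SimulatedEtg:
    """NB transcript counts for target/control pairs under per-sample eta.

    Control counts ~ NB(baseline_g * depth * lib, theta) with log-normal gene
    baselines; target counts use the same mean times exp(-eta_sample).
    ``samples`` may supply a pre-built sample frame (columns ``eta`` and
    ``library_factor``), e.g. with planted copy-number eta adjustments.
    """
    rng = component_rng(spec.seed, "etg")
    if samples is None:
        samples = spec.sample_frame()
    baselines = rng.lognormal(0.0, 0.5, n_pairs)
    lengths = rng.integers(500, 5000, size=2 * n_pairs)

    pair_rows, index = [], []
    for g in range(n_pairs):
        gid = f"G{g:04d}"
        pair_rows.append(
            {"gene_id": gid, "target_id": f"{gid}.t1", "control_id": f"{gid}.t2"}
        )
        index += [f"{gid}.t1", f"{gid}.t2"]

    eta = samples["eta"].to_numpy()
    lib = samples["library_factor"].to_numpy()
    n_s = len(samples)
    counts = np.zeros((2 * n_pairs, n_s), dtype=int)
    for g in range(n_pairs):
        mean_ctrl = baselines[g] * spec.depth * lib
        counts[2 * g] = _nb_draw(rng, mean_ctrl * np.exp(-eta), spec.theta)  # target
        counts[2 * g + 1] = _nb_draw(rng, mean_ctrl, spec.theta)  # control
    df = pd.DataFrame(counts, index=index, columns=samples.index)
    manifest = GroundTruthManifest(
        eta=dict(samples["eta"]),
        seeds={"global": spec.seed, "component": "etg"},
        pairs=pair_rows,
        extra={"gene_baselines": baselines.tolist(), "theta": spec.theta, "depth": spec.depth},
    )
    return SimulatedEtg(
        counts=df,
        pairs=pd.DataFrame(pair_rows),
        transcript_lengths=pd.Series(lengths, index=index),
        samples=samples,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# ASE counts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAse:
    variants: pd.DataFrame  # one row per (individual, variant)
    samples: pd.DataFrame
    manifest: GroundTruthManifest


def simulate_ase_counts(
    spec: CohortSpec,
    n_variants_per_individual: int = 10,
    class_mix: dict[str, float] | None = None,
    include_violations: bool = False,
    samples: pd.DataFrame | None = None,
) -> SimulatedAse:
    """Allele-specific counts at germline PTC loci under per-sample eta.

    WT ~ NB(depth * lib, theta); MUT uses mean * exp(-eta) for triggering
    PTCs and ratio 1 for evading / synonymous variants.  With
    ``include_violations`` each individual additionally receives one variant
    per violation type (coverage below threshold, MAF 25%, homozygous,
    non-PASS), truth-flagged in ``planted_violation``.
    """
    mix = class_mix or {"triggering": 1.0}
    rng = component_rng(spec.seed, "ase")
    if samples is None:
        samples = spec.sample_frame()
    rows = []
    for sid, srow in samples.iterrows():
        eta = srow["eta"]
        lib = srow["library_factor"]
        classes = rng.choice(
            list(mix.keys()), size=n_variants_per_individual, p=list(mix.values())
        )
        for v, cls in enumerate(classes):
            wt = int(_nb_draw(rng, spec.depth * lib, spec.theta))
            factor = np.exp(-eta) if cls == "triggering" else 1.0
            mut = int(_nb_draw(rng, spec.depth * lib * factor, spec.theta))
            rows.append(
                {
                    "individual_id": sid,
                    "variant_id": f"{sid}:v{v:03d}",
                    "gene_id": f"GA{v:03d}",
                    "transcript_id": f"GA{v:03d}.t1",
                    "variant_class": "nonsense" if cls != "synonymous" else "synonymous",
                    "nmd_class": cls if cls != "synonymous" else "none",
                    "ptc_cds_pos_nt": 300 if cls != "synonymous" else np.nan,
                    "filter_status": "PASS",
                    "heterozygous": True,
                    "population_maf": float(rng.uniform(0.0, 0.15)),
                    "gene_loeuf_percentile": float(rng.uniform(0.15, 1.0)),
                    "wt_count": wt,
                    "mut_count": mut,
                    "planted_violation": "",
                }
            )
        if include_violations:
            base = {
                "individual_id": sid,
                "gene_id": "GV000",
                "transcript_id": "GV000.t1",
                "variant_class": "nonsense",
                "nmd_class": "triggering",
                "ptc_cds_pos_nt": 300,
                "filter_status": "PASS",
                "heterozygous": True,
                "population_maf": 0.01,
                "gene_loeuf_percentile": 0.5,
                "wt_count": 30,
                "mut_count": 10,
            }
            for j, (viol, patch) in enumerate(
                [
                    ("low_coverage", {"wt_count": 2, "mut_count": 2}),
                    ("high_maf", {"population_maf": 0.25}),
                    ("homozygous", {"heterozygous": False}),
                    ("not_pass", {"filter_status": "LowQual"}),
                ]
            ):
                rows.append(
                    {**base, **patch, "variant_id": f"{sid}:bad{j}", "planted_violation": viol}
                )
    variants = pd.DataFrame(rows)
    manifest = GroundTruthManifest(
        eta=dict(samples["eta"]),
        seeds={"global": spec.seed, "component": "ase"},
        variant_truth=variants[["individual_id", "variant_id", "nmd_class", "planted_violation"]],
        extra={"theta": spec.theta, "depth": spec.depth},
    )
    return SimulatedAse(variants=variants, samples=samples, manifest=manifest)


# ---------------------------------------------------------------------------
# CNA matrices
# ---------------------------------------------------------------------------

@dataclass
class PlantedSegment:
    start_gene: int
    end_gene: int  # half-open gene-index range
    carrier_fraction: float
    eta_effect: float = 0.0
    score: float = 1.0


@dataclass
class SimulatedCna:
    cna: pd.DataFrame  # genes x samples
    gene_coords: pd.DataFrame
    carriers: pd.DataFrame  # samples x segments (bool)
    eta_adjustment: pd.Series  # per-sample eta decrement/increment
    manifest: GroundTruthManifest


def simulate_cna_matrix(
    n_genes: int,
    n_samples: int,
    planted_segments: list[PlantedSegment],
    seed: int = 0,
    noise_sd: float = 0.05,
    chrom: str = "chr1",
) -> SimulatedCna:
    """GISTIC-style dosage matrix with planted contiguous segments.

    Carriers of a segment receive score ~ N(segment.score, 0.1) across its
    genes; background is N(0, noise_sd).  The per-sample eta adjustment sums
    the ``eta_effect`` of carried segments.  Overlapping segments raise.
    """
    spans = sorted((s.start_gene, s.end_gene) for s in planted_segments)
    for (a1, b1), (a2, b2) in zip(spans[:-1], spans[1:]):
        if a2 < b1:
            raise ValueError("planted segments overlap")
    for s in planted_segments:
        if not (0 <= s.start_gene < s.end_gene <= n_genes):
            raise ValueError("segment outside gene range")

    rng = component_rng(seed, "cna")
    genes = [f"CG{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    mat = rng.normal(0.0, noise_sd, (n_genes, n_samples))
    carriers = {}
    eta_adj = np.zeros(n_samples)
    for k, seg in enumerate(planted_segments):
        is_carrier = rng.random(n_samples) < seg.carrier_fraction
        carriers[f"segment_{k}"] = is_carrier
        idx = np.where(is_carrier)[0]
        block = rng.normal(seg.score, 0.1, (seg.end_gene - seg.start_gene, len(idx)))
        mat[seg.start_gene : seg.end_gene, idx] += block
        eta_adj[is_carrier] += seg.eta_effect
    cna = pd.DataFrame(mat, index=genes, columns=sample_ids)
    coords = pd.DataFrame(
        {"chrom": chrom, "start": np.arange(n_genes) * 100_000}, index=genes
    )
    manifest = GroundTruthManifest(
        seeds={"global": seed, "component": "cna"},
        planted_segments=[s.__dict__ for s in planted_segments],
        extra={"noise_sd": noise_sd},
    )
    return SimulatedCna(
        cna=cna,
        gene_coords=coords,
        carriers=pd.DataFrame(carriers, index=sample_ids),
        eta_adjustment=pd.Series(eta_adj, index=sample_ids),
        manifest=manifest,
    )
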