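"""Transcript models and coordinate arithmetic.

A :class:`TranscriptModel` holds the exon/CDS structure of one transcript.
Genomic intervals are stored 0-based half-open; GTF input (1-based closed) is
converted on parse.  Exons are kept sorted 5'->3' in *transcript* orientation,
i.e. for minus-strand transcripts the first exon is the one with the largest
genomic coordinate.  CDS offsets are transcript coordinates (nt from the
spliced 5' end) and include the stop codon.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)


@dataclass
class TranscriptModel:
    """Exon/CDS structure of a single transcript.

    Parameters
    ----------
    exons
        Genomic ``(start, end)`` intervals, 0-based half-open, ordered 5'->3'
        in transcript orientation (descending genomic order on minus strand).
    cds_start, cds_end
        Transcript-coordinate offsets of the CDS (stop codon included), with
        ``0 <= cds_start < cds_end <= transcript_length``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    biotype: str = "protein_coding"
    _cum: list[int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        lengths = [e - s for s, e in self.exons]
        if any(l <= 0 for l in lengths):
            raise ValueError("empty or inverted exon interval")
        cum = [0]
        for l in lengths:
            cum.append(cum[-1] + l)
        self._cum = cum
        if not (0 <= self.cds_start < self.cds_end <= self.transcript_length):
            raise ValueError(
                f"{self.transcript_id}: CDS [{self.cds_start},{self.cds_end}) "
                f"outside transcript of length {self.transcript_length}"
            )

    # -- lengths ---------------------------------------------------------
    @property
    def transcript_length(self) -> int:
        """Total spliced length (sum of exon lengths, nt)."""
        return self._cum[-1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    # -- coordinate conversion ------------------------------------------
    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position (0-based) to a transcript offset.

        Raises ``ValueError`` for intronic / out-of-range positions.
        """
        for i, (s, e) in enumerate(self.exons):
            if s <= gpos < e:
                if self.strand == "+":
                    return self._cum[i] + (gpos - s)
                return self._cum[i] + (e - 1 - gpos)
        raise ValueError(f"position {gpos} not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, tpos: int) -> int:
        """Inverse of :meth:`genomic_to_transcript`."""
        if not 0 <= tpos < self.transcript_length:
            raise ValueError(f"transcript offset {tpos} out of range")
        i = bisect_right(self._cum, tpos) - 1
        off = tpos - self._cum[i]
        s, e = self.exons[i]
        return s + off if self.strand == "+" else e - 1 - off

    def exon_index_of(self, tpos: int) -> int:
        """Index (0-based, transcript order) of the exon containing ``tpos``."""
        if not 0 <= tpos < self.transcript_length:
            raise ValueError(f"transcript offset {tpos} out of range")
        return bisect_right(self._cum, tpos) - 1

    def junction_positions(self) -> list[int]:
        """Transcript offsets of exon-exon junctions (nt 5' of each junction)."""
        return list(self._cum[1:-1])

    # -- sequence --------------------------------------------------------
    def spliced_sequence(self, genome) -> str:
        """Spliced transcript sequence, 5'->3', from an indexed FASTA.

        ``genome`` is a mapping of chromosome name to sliceable sequence
        (e.g. a :class:`pyfaidx.Fasta` or a plain dict of strings).
        """
        chrom = genome[self.chrom]
        parts = []
        for s, e in self.exons:
            seg = str(chrom[s:e])
            if self.strand == "-":
                seg = str(Seq(seg).reverse_complement())
            parts.append(seg)
        return "".join(parts).upper()

    def cds_sequence(self, genome) -> str:
        return self.spliced_sequence(genome)[self.cds_start : self.cds_end]

    def utr5_sequence(self, genome) -> str:
        return self.spliced_sequence(genome)[: self.cds_start]

    def utr3_sequence(self, genome) -> str:
        return self.spliced_sequence(genome)[self.cds_end :]


def _tx_sort_key(model: TranscriptModel):
    return (model.chrom, model.exons[0][0], model.transcript_id)


def parse_transcript_models(
    annotation_file: str,
    sequence_file: str | None = None,
    include_stop_codon: bool = True,
) -> list[TranscriptModel]:
    """Parse coding transcript models from a GTF file.

    One :class:`TranscriptModel` is returned per transcript with at least one
    CDS record; transcripts without CDS are skipped with a warning.  GTF
    1-based closed intervals are converted to 0-based half-open.  ``stop_codon``
    features, when present, are merged into the CDS so that transcript CDS
    coordinates always include the stop codon.

    Raises ``ValueError`` if ``sequence_file`` is given and a referenced
    chromosome is missing from it.
    """
    db = gffutils.create_db(
        annotation_file,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genome = Fasta(sequence_file) if sequence_file else None

    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        gid = feat.attributes.get("gene_id", [tid])[0]
        biotype = (
            feat.attributes.get("transcript_biotype", [None])[0]
            or feat.attributes.get("transcript_type", ["protein_coding"])[0]
        )
        meta[tid] = (gid, feat.seqid, feat.strand, biotype)
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        if feat.featuretype == "exon":
            exons.setdefault(tid, []).append(iv)
        else:
            if feat.featuretype == "stop_codon" and not include_stop_codon:
                continue
            cds.setdefault(tid, []).append(iv)

    models = []
    for tid, ex in exons.items():
        gid, chrom, strand, biotype = meta[tid]
        if tid not in cds:
            logger.warning("transcript %s has no CDS record; skipped", tid)
            continue
        if genome is not None and chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from sequence file")
        ex = sorted(set(ex))
        cds_iv = _merge_intervals(sorted(cds[tid]))
        if strand == "-":
            ex = ex[::-1]
        model_ex = ex
        # transcript-coordinate CDS bounds
        cum = [0]
        for s, e in model_ex:
            cum.append(cum[-1] + (e - s))
        g_cds_lo = min(s for s, _ in cds_iv)
        g_cds_hi = max(e for _, e in cds_iv)
        tmp = TranscriptModel(tid, gid, chrom, strand, model_ex, 0, cum[-1], biotype)
        if strand == "+":
            t_start = tmp.genomic_to_transcript(g_cds_lo)
            t_end = tmp.genomic_to_transcript(g_cds_hi - 1) + 1
        else:
            t_start = tmp.genomic_to_transcript(g_cds_hi - 1)
            t_end = tmp.genomic_to_transcript(g_cds_lo) + 1
        models.append(
            TranscriptModel(tid, gid, chrom, strand, model_ex, t_start, t_end, biotype)
        )
    models.sort(key=_tx_sort_key)
    return models


def _merge_intervals(ivs):
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def transcripts_overlapping(
    models: list[TranscriptModel], intervals: list[tuple[str, int, int]]
) -> set[str]:
    """Ids of transcripts whose exon span overlaps any (chrom, start, end) interval.

    Used to translate per-individual truncating-variant / copy-number exclusion
    tracks into transcript exclusions for the count-based estimator.
    """
    hit = set()
    for m in models:
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        for chrom, s, e in intervals:
            if chrom == m.chrom and s < hi and lo < e:
                hit.add(m.transcript_id)
                break
    return hit
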