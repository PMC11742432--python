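"""Candidate-site construction from nanopore-derived per-read tables.

m6A occurs almost exclusively in the RRACH sequence context (R = A/G,
H = A/C/T, the central A being the methylated base).  This module scans
reference transcripts for RRACH windows, gathers each covering read's raw
signal samples and base-call record over the five motif positions, and
assembles one 40-dimensional feature vector per read:

    20 signal features  — median, population SD, mean, sample count of the
                          raw current samples at positions -2..+2;
    20 alignment features — mean base quality, mismatch, insertion and
                          deletion indicators at positions -2..+2.

Sites are kept only if covered by at least ``min_reads`` reads (3, 5 and 20
are the conventional thresholds).  Two upstream table dialects are read:
an eventalign-like signal table (dialect A) and a sam2tsv-like per-base
alignment table (dialect B); the long-format 40-feature TSV of the bags
module is the native dialect C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .bags import InstanceFeature, SiteBag

N_MOTIF = 5          # RRACH window width
N_FEATURES = 40      # 4 signal + 4 alignment stats at each of 5 positions

# columns holding signal level and spread statistics (median, SD, mean per
# position) in the 40-feature layout; within-site centering of these
# compares each read to the site consensus, removing 5-mer-specific current
# offsets and noise scales that would otherwise fingerprint the motif class
SIGNAL_LOCATION_IDX = tuple(4 * i + j for i in range(5) for j in (0, 1, 2))

_RRACH = re.compile(r"(?=([AG][AG]AC[ACT]))")
_IUPAC = set("ACGTURYSWKMBDHVN")


@dataclass(frozen=True)
class MotifSite:
    transcript_id: str
    center_pos: int          # 0-based transcript coordinate of the A
    kmer: str

    @property
    def bag_id(self) -> str:
        return f"{self.transcript_id}:{self.center_pos}"


@dataclass
class BaseCall:
    base: str                # called base, "." if deleted
    quality: float           # phred; 0 if deleted
    insertion: bool = False  # insertion adjacent to this base in the read
    deletion: bool = False


@dataclass
class ReadSiteEvents:
    """One read's raw material at one motif window: 5 sample lists + 5 calls."""

    read_id: str
    samples: list[np.ndarray]   # raw-signal samples per motif position
    calls: list[BaseCall]

    def __post_init__(self) -> None:
        if len(self.samples) != N_MOTIF or len(self.calls) != N_MOTIF:
            raise ValueError("ReadSiteEvents needs exactly 5 base slots")
        self.samples = [np.asarray(s, dtype=float) for s in self.samples]
        for s, c in zip(self.samples, self.calls):
            if s.size == 0 and not c.deletion:
                raise ValueError(
                    f"read {self.read_id!r}: empty sample list at a non-deleted base"
                )


def normalize_sequence(sequence: str) -> str:
    """Uppercase and map U -> T."""
    return sequence.upper().replace("U", "T")


def scan_rrach(sequence: str, transcript_id: str) -> list[MotifSite]:
    """All RRACH windows in a transcript, centered on the A (0-based).

    Overlapping windows are all reported.  Characters outside the IUPAC
    nucleotide alphabet raise an error naming the first offending position.
    """
    seq = normalize_sequence(sequence)
    for i, ch in enumerate(seq):
        if ch not in _IUPAC:
            raise ValueError(f"invalid character {ch!r} at position {i} in {transcript_id!r}")
    return [
        MotifSite(transcript_id, m.start() + 2, m.group(1))
        for m in _RRACH.finditer(seq)
    ]


def scan_fasta(path: str | Path) -> tuple[dict[str, str], list[MotifSite]]:
    """Read transcript references and scan each for RRACH sites."""
    seqs: dict[str, str] = {}
    sites: list[MotifSite] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        seqs[rec.id] = seq
        sites.extend(scan_rrach(seq, rec.id))
    return seqs, sites


def signal_features(events: ReadSiteEvents) -> np.ndarray:
    """Median, population SD, mean, count of raw samples per motif position.

    A deleted base contributes the sentinel (0, 0, 0, 0).
    """
    out = np.zeros(4 * N_MOTIF)
    for i, s in enumerate(events.samples):
        if s.size == 0:
            continue
        out[4 * i: 4 * i + 4] = (np.median(s), s.std(), s.mean(), s.size)
    return out


def alignment_features(events: ReadSiteEvents, kmer: str) -> np.ndarray:
    """Quality / mismatch / insertion / deletion per motif position.

    Mismatch, insertion and deletion are per-read 0/1 indicators; a deleted
    base reports quality 0, mismatch 0, deletion 1.
    """
    out = np.zeros(4 * N_MOTIF)
    for i, call in enumerate(events.calls):
        if call.deletion:
            out[4 * i: 4 * i + 4] = (0.0, 0.0, float(call.insertion), 1.0)
        else:
            mism = float(call.base != kmer[i])
            out[4 * i: 4 * i + 4] = (call.quality, mism, float(call.insertion), 0.0)
    return out


def read_feature_vector(events: ReadSiteEvents, kmer: str) -> np.ndarray:
    """The 40-feature instance: 20 signal values then 20 alignment values."""
    return np.concatenate([signal_features(events), alignment_features(events, kmer)])


def build_site_bags(
    sites: Sequence[MotifSite],
    per_read_events: Mapping[str, Sequence[ReadSiteEvents]],
    min_reads: int = 5,
    site_truth: Mapping[str, int] | None = None,
    read_truth: Mapping[tuple[str, str], int] | None = None,
) -> tuple[list[SiteBag], dict[str, int]]:
    """One bag per site with >= min_reads covering reads.

    ``per_read_events`` maps bag_id ("transcript:pos") to that site's reads.
    Optional truth maps attach hidden site / read labels (synthetic data and
    evaluation).  Returns the bags and a report of kept/dropped site counts.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    bags: list[SiteBag] = []
    kept = dropped = 0
    for site in sites:
        reads = per_read_events.get(site.bag_id, ())
        if len(reads) < min_reads:
            if reads:
                dropped += 1
            continue
        kept += 1
        insts = []
        for ev in reads:
            hidden = None
            if read_truth is not None:
                hidden = read_truth.get((site.bag_id, ev.read_id))
            insts.append(InstanceFeature(ev.read_id,
                                         read_feature_vector(ev, site.kmer),
                                         hidden_label=hidden))
        hidden_bag = site_truth.get(site.bag_id) if site_truth is not None else None
        bags.append(SiteBag(site.bag_id, insts, hidden_bag_label=hidden_bag))
    return bags, {"sites_kept": kept, "sites_dropped": dropped}


# ---------------------------------------------------------------------------
# Dialect A: eventalign-like signal table.
# Columns: contig, position, reference_kmer, read_name, event_level_mean,
# event_stdv, samples (comma-joined raw samples).  Multiple rows per
# (read, position) are concatenated in file order.


def read_eventalign(path: str | Path) -> dict[tuple[str, int, str], np.ndarray]:
    """Per-(contig, position, read) raw sample arrays from dialect A."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "read_name": str,
                                            "samples": str})
    out: dict[tuple[str, int, str], list[float]] = {}
    for contig, pos, read, samples in zip(df["contig"], df["position"],
                                          df["read_name"], df["samples"]):
        key = (contig, int(pos), read)
        vals = [float(x) for x in str(samples).split(",") if x != ""]
        out.setdefault(key, []).extend(vals)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Dialect B: sam2tsv-like per-base alignment table.
# Columns: read_name, contig, ref_pos, read_base, ref_base, base_qual,
# cigar_op.  Deletions carry read_base "." and op "D"; an insertion directly
# following a base is flagged on that base's row via op "I" rows sharing its
# ref_pos.


def read_sam2tsv(path: str | Path) -> dict[tuple[str, int, str], BaseCall]:
    """Per-(contig, ref_pos, read) base calls from dialect B."""
    df = pd.read_csv(path, sep="\t", dtype={"read_name": str, "contig": str,
                                            "read_base": str, "ref_base": str,
                                            "cigar_op": str})
    calls: dict[tuple[str, int, str], BaseCall] = {}
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.ref_pos), row.read_name)
        if row.cigar_op == "I":
            if key in calls:
                calls[key].insertion = True
            else:  # insertion seen before the match row
                calls[key] = BaseCall(".", 0.0, insertion=True, deletion=True)
            continue
        deletion = row.cigar_op == "D"
        prev = calls.get(key)
        call = BaseCall(
            base="." if deletion else str(row.read_base),
            quality=0.0 if deletion else float(row.base_qual),
            insertion=prev.insertion if prev else False,
            deletion=deletion,
        )
        calls[key] = call
    return calls


def assemble_read_events(
    sites: Sequence[MotifSite],
    signal_index: Mapping[tuple[str, int, str], np.ndarray],
    call_index: Mapping[tuple[str, int, str], BaseCall],
) -> dict[str, list[ReadSiteEvents]]:
    """Join dialect A and B indexes into per-site read events.

    A read covers a site when it has a call record at all five motif
    positions (deleted bases count as covered).
    """
    touch: dict[tuple[str, int], list[MotifSite]] = {}
    for site in sites:
        for pos in range(site.center_pos - 2, site.center_pos + 3):
            touch.setdefault((site.transcript_id, pos), []).append(site)

    reads_by_site: dict[str, set[str]] = {}
    for (contig, pos, read) in call_index:
        for site in touch.get((contig, pos), ()):
            reads_by_site.setdefault(site.bag_id, set()).add(read)

    site_by_id = {s.bag_id: s for s in sites}
    out: dict[str, list[ReadSiteEvents]] = {}
    for bag_id, reads in reads_by_site.items():
        site = site_by_id[bag_id]
        positions = range(site.center_pos - 2, site.center_pos + 3)
        for read in sorted(reads):
            calls, samples, complete = [], [], True
            for pos in positions:
                call = call_index.get((site.transcript_id, pos, read))
                if call is None:
                    complete = False
                    break
                calls.append(BaseCall(call.base, call.quality,
                                      call.insertion, call.deletion))
                s = signal_index.get((site.transcript_id, pos, read),
                                     np.empty(0))
                samples.append(np.asarray(s, dtype=float))
            if not complete:
                continue
            # a non-deleted base with no samples cannot form a valid event
            if any(s.size == 0 and not c.deletion
                   for s, c in zip(samples, calls)):
                continue
            out.setdefault(bag_id, []).append(
                ReadSiteEvents(read, samples, calls))
    return out


# ---------------------------------------------------------------------------
# Outputs


def write_predictions(path: str | Path, predictions, sites: Sequence[MotifSite],
                      bed_path: str | Path | None = None) -> None:
    """Predictions TSV (transcript_id, center_pos, kmer, n_reads, site_prob)
    and optional BED6 with score = 1000 * site_prob."""
    site_by_id = {s.bag_id: s for s in sites}
    rows, bed_rows = [], []
    for pred in predictions:
        site = site_by_id.get(pred.bag_id)
        tid, pos = pred.bag_id.rsplit(":", 1)
        kmer = site.kmer if site else "NNNNN"
        rows.append({"transcript_id": tid, "center_pos": int(pos), "kmer": kmer,
                     "n_reads": pred.n_reads,
                     "site_prob": round(pred.site_prob, 6)})
        bed_rows.append((tid, int(pos), int(pos) + 1, kmer,
                         int(round(1000 * pred.site_prob)), "+"))
    pd.DataFrame(rows, columns=["transcript_id", "center_pos", "kmer",
                                "n_reads", "site_prob"]
                 ).to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in bed_rows:
                fh.write("\t".join(str(x) for x in r) + "\n")
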