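"""Synthetic data generators for end-to-end testing without downloads.

Two generators:

* :func:`gen_mil_bags` — generic PU-MIL benchmark bags: negative bags draw
  every instance from a background Gaussian, positive bags replace a
  configurable fraction of instances with mean-shifted ones.  The shift is
  expressed in population-SD units, so ``class_separation`` is directly an
  effect size.

* :func:`gen_m6a_dataset` — ONT-like site bags: random transcripts are
  scanned for RRACH windows; a subset of sites is designated modified; at a
  modified site a stoichiometry fraction of reads carries a current-level
  shift at the central base plus base-calling error inflation (lower
  quality, more mismatches/deletions).  Per-5-mer current means come from a
  seeded stand-in pore-model table; dwell (samples per base) is geometric.
  The dataset can be emitted as the eventalign-like (A), sam2tsv-like (B)
  and native long-format (C) dialects plus FASTA and truth TSVs, and
  ingested back through the feature builder.

Modified and unmodified reads are statistically indistinguishable when both
``signal_shift_sd`` and ``error_inflation`` are zero — the null case used
for calibration tests.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .bags import InstanceFeature, SiteBag
from .features import (BaseCall, MotifSite, ReadSiteEvents, build_site_bags,
                       scan_rrach)

PORE_MODEL_SEED = 4099  # fixed: the stand-in pore model is a property of the
                        # generator, not of an individual dataset


@lru_cache(maxsize=1)
def pore_model() -> dict[str, tuple[float, float]]:
    """Stand-in pore model: (current mean in pA, SD) for every 5-mer."""
    rng = np.random.default_rng(PORE_MODEL_SEED)
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=5)]
    means = rng.uniform(80.0, 120.0, size=len(kmers))
    sds = rng.uniform(1.5, 3.0, size=len(kmers))
    return {k: (float(m), float(s)) for k, m, s in zip(kmers, means, sds)}


# ---------------------------------------------------------------------------
# Generic MIL bags


@dataclass
class MilGenConfig:
    n_bags: int = 100
    bag_size_range: tuple[int, int] = (5, 15)
    instance_dim: int = 10
    positive_instance_rate: float = 0.3   # fraction of instances shifted in + bags
    class_separation: float = 2.0         # mean shift, population-SD units
    positive_bag_fraction: float = 0.5
    seed: int = 0


def gen_mil_bags(config: MilGenConfig) -> list[SiteBag]:
    """Fully-labeled synthetic MIL bags with known instance labels.

    The bag label is the OR of the instance labels by construction.
    """
    if config.positive_instance_rate <= 0:
        raise ValueError(
            "positive_instance_rate must be > 0: a positive bag must contain "
            "at least one positive instance"
        )
    if config.class_separation < 0:
        raise ValueError("class_separation must be >= 0")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bag_size_range
    n_pos_bags = int(round(config.positive_bag_fraction * config.n_bags))
    # positive instances shift along the first coordinate; background is N(0, 1)
    shift = np.zeros(config.instance_dim)
    shift[0] = config.class_separation
    bags = []
    for b in range(config.n_bags):
        positive_bag = b < n_pos_bags
        k = int(rng.integers(lo, hi + 1))
        X = rng.normal(size=(k, config.instance_dim))
        labels = np.zeros(k, dtype=int)
        if positive_bag:
            n_pos = max(1, int(round(config.positive_instance_rate * k)))
            idx = rng.choice(k, size=n_pos, replace=False)
            X[idx] += shift
            labels[idx] = 1
        insts = [
            InstanceFeature(f"bag{b}_inst{i}", X[i], hidden_label=int(labels[i]))
            for i in range(k)
        ]
        bags.append(SiteBag(f"bag{b}", insts, hidden_bag_label=int(labels.any())))
    # shuffle bag order so positives are not a prefix
    order = rng.permutation(len(bags))
    return [bags[i] for i in order]


# ---------------------------------------------------------------------------
# ONT-like m6A site bags


@dataclass
class M6aGenConfig:
    n_transcripts: int = 10
    transcript_length: int = 400
    mod_site_fraction: float = 0.5        # fraction of RRACH sites modified
    stoichiometry: tuple[float, float] = (0.4, 0.9)  # per-site modified-read fraction
    reads_per_site: tuple[int, int] = (10, 30)
    signal_shift_sd: float = 2.0          # center-base current shift, SD units
    error_inflation: float = 0.5          # mismatch/quality degradation scale
    dwell_mean: float = 8.0               # mean raw samples per base
    seed: int = 0


@dataclass
class M6aDataset:
    transcripts: dict[str, str]
    sites: list[MotifSite]
    events: dict[str, list[ReadSiteEvents]]   # bag_id -> reads
    site_truth: dict[str, int]                # bag_id -> modified?
    read_truth: dict[tuple[str, str], int]    # (bag_id, read_id) -> modified?
    config: M6aGenConfig

    def to_bags(self, min_reads: int = 5) -> tuple[list[SiteBag], dict[str, int]]:
        return build_site_bags(self.sites, self.events, min_reads,
                               site_truth=self.site_truth,
                               read_truth=self.read_truth)


def _draw_dwell(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / mean))


def gen_m6a_dataset(config: M6aGenConfig) -> M6aDataset:
    """Simulate transcripts, RRACH sites and per-read events; byte-stable
    under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    model = pore_model()
    transcripts: dict[str, str] = {}
    sites: list[MotifSite] = []
    for t in range(config.n_transcripts):
        tid = f"tx{t}"
        seq = "".join(rng.choice(list("ACGT"), size=config.transcript_length))
        transcripts[tid] = seq
        sites.extend(scan_rrach(seq, tid))

    lo_s, hi_s = config.stoichiometry
    lo_r, hi_r = config.reads_per_site
    events: dict[str, list[ReadSiteEvents]] = {}
    site_truth: dict[str, int] = {}
    read_truth: dict[tuple[str, str], int] = {}
    for site in sites:
        modified_site = bool(rng.random() < config.mod_site_fraction)
        site_truth[site.bag_id] = int(modified_site)
        stoich = float(rng.uniform(lo_s, hi_s)) if modified_site else 0.0
        depth = int(rng.integers(lo_r, hi_r + 1))
        n_mod = max(1, int(round(stoich * depth))) if modified_site else 0
        mod_flags = np.zeros(depth, dtype=bool)
        if n_mod:
            mod_flags[rng.choice(depth, size=n_mod, replace=False)] = True
        reads = []
        for r in range(depth):
            read_id = f"{site.bag_id}_read{r}"
            reads.append(_simulate_read(rng, site, bool(mod_flags[r]),
                                        config, model, read_id))
            read_truth[(site.bag_id, read_id)] = int(mod_flags[r])
        events[site.bag_id] = reads
    return M6aDataset(transcripts, sites, events, site_truth, read_truth, config)


def _simulate_read(rng: np.random.Generator, site: MotifSite, modified: bool,
                   cfg: M6aGenConfig, model: dict, read_id: str) -> ReadSiteEvents:
    samples, calls = [], []
    e = cfg.error_inflation if modified else 0.0
    for offset in range(-2, 3):
        ref_base = site.kmer[offset + 2]
        # 5-mer context centered on this base, clipped at the motif edge
        context = site.kmer[max(0, offset): offset + 5].ljust(5, ref_base)[:5]
        mean, sd = model[context]
        if modified and offset == 0:
            mean += cfg.signal_shift_sd * sd
        at_center = offset == 0
        p_del = 0.01 + (0.08 * e if at_center else 0.0)
        p_mis = 0.02 + (0.30 * e if at_center else 0.0)
        p_ins = 0.01 + (0.05 * e if at_center else 0.0)
        deleted = bool(rng.random() < p_del)
        if deleted:
            samples.append(np.empty(0))
            calls.append(BaseCall(".", 0.0, insertion=False, deletion=True))
            continue
        n = _draw_dwell(rng, cfg.dwell_mean)
        samples.append(rng.normal(mean, sd, size=n))
        if rng.random() < p_mis:
            base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        else:
            base = ref_base
        qual = float(np.clip(rng.normal(30.0 - (10.0 * e if at_center else 0.0), 3.0),
                             2.0, 40.0))
        calls.append(BaseCall(base, round(qual, 2),
                              insertion=bool(rng.random() < p_ins),
                              deletion=False))
    return ReadSiteEvents(read_id, samples, calls)


# ---------------------------------------------------------------------------
# File emission (dialects A/B, FASTA, truth)


def write_m6a_dataset(ds: M6aDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, dialect A/B tables, truth TSVs and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "eventalign": outdir / "signal.eventalign.tsv",
        "sam2tsv": outdir / "alignment.sam2tsv.tsv",
        "site_truth": outdir / "site_truth.tsv",
        "read_truth": outdir / "read_truth.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["fasta"], "w") as fh:
        for tid, seq in ds.transcripts.items():
            fh.write(f">{tid}\n{seq}\n")

    site_by_id = {s.bag_id: s for s in ds.sites}
    a_rows, b_rows = [], []
    for bag_id, reads in ds.events.items():
        site = site_by_id[bag_id]
        for ev in reads:
            for offset, (s, call) in enumerate(zip(ev.samples, ev.calls)):
                pos = site.center_pos + offset - 2
                if s.size:
                    a_rows.append({
                        "contig": site.transcript_id, "position": pos,
                        "reference_kmer": site.kmer, "read_name": ev.read_id,
                        "event_level_mean": round(float(s.mean()), 4),
                        "event_stdv": round(float(s.std()), 4),
                        "samples": ",".join(f"{x:.3f}" for x in s),
                    })
                b_rows.append({
                    "read_name": ev.read_id, "contig": site.transcript_id,
                    "ref_pos": pos, "read_base": call.base,
                    "ref_base": site.kmer[offset],
                    "base_qual": call.quality,
                    "cigar_op": "D" if call.deletion else "M",
                })
                if call.insertion:
                    b_rows.append({
                        "read_name": ev.read_id, "contig": site.transcript_id,
                        "ref_pos": pos, "read_base": "N",
                        "ref_base": ".", "base_qual": 10.0, "cigar_op": "I",
                    })
    pd.DataFrame(a_rows).to_csv(paths["eventalign"], sep="\t", index=False)
    pd.DataFrame(b_rows).to_csv(paths["sam2tsv"], sep="\t", index=False)
    pd.DataFrame(
        [{"bag_id": k, "label": v} for k, v in ds.site_truth.items()]
    ).to_csv(paths["site_truth"], sep="\t", index=False)
    pd.DataFrame(
        [{"bag_id": b, "read_id": r, "label": v}
         for (b, r), v in ds.read_truth.items()]
    ).to_csv(paths["read_truth"], sep="\t", index=False)
    manifest = {"generator": "m6a", "config": asdict(ds.config),
                "n_sites": len(ds.sites)}
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
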