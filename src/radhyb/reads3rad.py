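"""The bespoke 3RAD read-processing chain.

Stages, in pipeline order: in-line barcode demultiplexing, PCR-duplicate
removal keyed on the random i5 tag plus the first 100 bp of each mate,
overlap merging with a minimum merged length, restriction-site checking
(keep MseI-cut fragments, discard CviQI-cut ones), quality trimming of
unmerged pairs, and removal of reads carrying a complete internal
restriction site.  Every stage reports input/kept/dropped counts and the
counts always conserve.

The restriction-site check runs before quality trimming because the
EcoRI-remnant anchor occupies the low-quality head of the reverse read
that trimming clips off.  Merged reads bypass quality trimming: they were
already consensus-called from both mates and a per-mate length cap does
not apply to them.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import pandas as pd

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: recognition sequences of the three library enzymes
RECOGNITION_SITES = {"MseI": "TTAA", "EcoRI": "GAATTC", "CviQI": "GTAC"}

#: post-cut remnants left at read starts after adapter ligation
MSEI_REMNANT = "TAA"
CVIQI_REMNANT = "TAC"
ECORI_REMNANT = "AATTC"


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class ReadPair:
    """One paired-end read with its i5 sequence tag.

    ``sample`` is None before demultiplexing and the sample id after;
    the in-line barcode is removed from the forward read at demux.
    """

    id: str
    fwd_seq: str
    fwd_qual: str
    rev_seq: str
    rev_qual: str
    i5: str
    sample: str | None = None

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: str
    i5: str
    sample: str | None = None


@dataclass
class FilterReport:
    """Per-stage accounting; kept + dropped = input at every stage."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_kept: int, drops: dict[str, int]) -> None:
        if n_kept + sum(drops.values()) != n_in:
            raise AssertionError(f"count conservation violated at stage {stage}")
        self.stages.append(
            {"stage": stage, "input": n_in, "kept": n_kept, "dropped": n_in - n_kept,
             **{f"drop_{k}": v for k, v in drops.items()}}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages).fillna(0)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- demux
def _hamming_leq(a: str, b: str, k: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


def demultiplex_inline(
    pairs: list[ReadPair],
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
    report: FilterReport | None = None,
) -> dict[str, list[ReadPair]]:
    """Assign pairs to samples by the forward-read in-line barcode.

    The barcode is trimmed from the forward read of assigned pairs.
    Barcodes must be unambiguous at the allowed mismatch radius: no
    barcode may match another barcode's prefix within ``max_mismatch``.
    """
    items = sorted(barcode_map.items())
    for i, (_, bi) in enumerate(items):
        for j, (_, bj) in enumerate(items):
            if i == j:
                continue
            short, long_ = sorted((bi, bj), key=len)
            if _hamming_leq(short, long_[: len(short)], 2 * max_mismatch):
                raise ValueError(
                    f"ambiguous barcode map: {bi!r} and {bj!r} collide at "
                    f"max_mismatch={max_mismatch}"
                )

    out: dict[str, list[ReadPair]] = {s: [] for s, _ in items}
    unassigned = 0
    for pair in pairs:
        hit = None
        for sample, bc in items:
            if len(pair.fwd_seq) >= len(bc) and _hamming_leq(
                pair.fwd_seq[: len(bc)], bc, max_mismatch
            ):
                hit = (sample, bc)
                break
        if hit is None:
            unassigned += 1
            continue
        sample, bc = hit
        out[sample].append(
            replace(
                pair,
                fwd_seq=pair.fwd_seq[len(bc):],
                fwd_qual=pair.fwd_qual[len(bc):],
                sample=sample,
            )
        )
    if report is not None:
        report.add(
            "demultiplex", len(pairs), len(pairs) - unassigned,
            {"unassigned": unassigned},
        )
    return out


# ------------------------------------------------------------ duplicates
def remove_pcr_duplicates(
    pairs: list[ReadPair], key_len: int = 100, report: FilterReport | None = None
) -> list[ReadPair]:
    """Keep one representative per (i5 tag, first 100 bp of each mate).

    The first occurrence is retained; reads shorter than the key window
    contribute their full sequence to the key.
    """
    seen: set[tuple[str, str, str]] = set()
    kept: list[ReadPair] = []
    for pair in pairs:
        key = (pair.i5, pair.fwd_seq[:key_len], pair.rev_seq[:key_len])
        if key in seen:
            continue
        seen.add(key)
        kept.append(pair)
    if report is not None:
        report.add(
            "pcr_duplicates", len(pairs), len(kept),
            {"duplicate": len(pairs) - len(kept)},
        )
    return kept


# --------------------------------------------------------------- merging
def _best_overlap(fwd: str, rev_rc: str, min_overlap: int, max_mismatch_frac: float):
    """Highest-scoring ungapped suffix(fwd)/prefix(rev_rc) overlap.

    Score = matches - mismatches; ties broken by the longest overlap.
    Returns (overlap_len, n_mismatch) or None.
    """
    best = None
    lim = min(len(fwd), len(rev_rc))
    nf = len(fwd)
    for k in range(min_overlap, lim + 1):
        limit = max_mismatch_frac * k
        mm = 0
        off = nf - k
        ok = True
        for i in range(k):
            if fwd[off + i] != rev_rc[i]:
                mm += 1
                if mm > limit:
                    ok = False
                    break
        if not ok:
            continue
        score = k - 2 * mm
        if best is None or score > best[0] or (score == best[0] and k > best[1]):
            best = (score, k, mm)
    if best is None:
        return None
    return best[1], best[2]


def merge_pairs(
    pairs: list[ReadPair],
    min_overlap: int = 30,
    min_merged_len: int = 240,
    max_mismatch_frac: float = 0.1,
    report: FilterReport | None = None,
) -> tuple[list[MergedRead], list[ReadPair]]:
    """Merge inward-facing mates whose overlap is at least ``min_overlap``.

    Conflicting overlap bases take the higher-quality call.  Merged reads
    shorter than ``min_merged_len`` are fragments below the library size
    selection and are dropped; non-overlapping pairs pass through intact.
    """
    merged: list[MergedRead] = []
    unmerged: list[ReadPair] = []
    n_short = 0
    for pair in pairs:
        rev_rc = revcomp(pair.rev_seq)
        rev_rc_q = pair.rev_qual[::-1]
        hit = _best_overlap(pair.fwd_seq, rev_rc, min_overlap, max_mismatch_frac)
        if hit is None:
            unmerged.append(pair)
            continue
        k, _ = hit
        head = pair.fwd_seq[: len(pair.fwd_seq) - k]
        head_q = pair.fwd_qual[: len(pair.fwd_seq) - k]
        tail = rev_rc[k:]
        tail_q = rev_rc_q[k:]
        ov_seq = []
        ov_q = []
        off = len(pair.fwd_seq) - k
        for i in range(k):
            fb, fq = pair.fwd_seq[off + i], pair.fwd_qual[off + i]
            rb, rq = rev_rc[i], rev_rc_q[i]
            if fb == rb or fq >= rq:
                ov_seq.append(fb)
                ov_q.append(max(fq, rq))
            else:
                ov_seq.append(rb)
                ov_q.append(rq)
        seq = head + "".join(ov_seq) + tail
        if len(seq) < min_merged_len:
            n_short += 1
            continue
        merged.append(
            MergedRead(pair.id, seq, head_q + "".join(ov_q) + tail_q, pair.i5, pair.sample)
        )
    if report is not None:
        report.add(
            "merge", len(pairs), len(merged) + len(unmerged),
            {"short_merged": n_short},
        )
    return merged, unmerged


# ------------------------------------------------------------- trimming
def _sliding_trim(seq: str, qual: str, q_min: int, window: int) -> int:
    """3' cut point: first base whose trailing window mean drops below q_min."""
    n = len(seq)
    if n == 0:
        return 0
    phred = [ord(c) - 33 for c in qual]
    for i in range(n):
        w = phred[i: i + window]
        if sum(w) / len(w) < q_min:
            return i
    return n


def quality_trim(
    pairs: list[ReadPair],
    q_min: int = 30,
    max_len: int = 130,
    rev_head_clip: int = 6,
    window: int = 4,
    min_survivor_len: int = 36,
    report: FilterReport | None = None,
) -> list[ReadPair]:
    """Quality-trim unmerged pairs (Phred+33).

    Both mates are 3'-trimmed where a sliding ``window``-bp mean quality
    falls below ``q_min`` and truncated to ``max_len``; the reverse mate
    then loses its low-quality ``rev_head_clip`` head (the bases occupied
    by the near-invariant EcoRI recognition site), so an all-high-quality
    150 bp pair comes out as 130 bp forward and 124 bp reverse.  Pairs
    with a mate shorter than ``min_survivor_len`` are dropped.
    """
    kept: list[ReadPair] = []
    n_short = 0
    for pair in pairs:
        for ch in pair.fwd_qual + pair.rev_qual:
            if not 33 <= ord(ch) < 127:
                raise ValueError(f"non-ASCII quality string in read {pair.id}")
        fcut = min(_sliding_trim(pair.fwd_seq, pair.fwd_qual, q_min, window), max_len)
        rcut = min(_sliding_trim(pair.rev_seq, pair.rev_qual, q_min, window), max_len)
        rseq = pair.rev_seq[rev_head_clip:rcut]
        rqual = pair.rev_qual[rev_head_clip:rcut]
        if fcut < min_survivor_len or len(rseq) < min_survivor_len:
            n_short += 1
            continue
        kept.append(
            replace(
                pair,
                fwd_seq=pair.fwd_seq[:fcut],
                fwd_qual=pair.fwd_qual[:fcut],
                rev_seq=rseq,
                rev_qual=rqual,
            )
        )
    if report is not None:
        report.add(
            "quality_trim", len(pairs), len(kept), {"low_quality": n_short}
        )
    return kept


# ----------------------------------------------------------- site checks
def check_cut_sites(
    pairs: list[ReadPair],
    keep_remnant: str = MSEI_REMNANT,
    drop_remnant: str = CVIQI_REMNANT,
    anchor_remnant: str = ECORI_REMNANT,
    require_anchor: bool = True,
    report: FilterReport | None = None,
) -> list[ReadPair]:
    """Keep MseI-cut pairs, discard CviQI-cut and siteless ones.

    The forward read (barcode already removed) must begin with the MseI
    remnant; a CviQI remnant start marks an unwanted fragment.  The
    reverse read is anchored on the EcoRI remnant, checked here - before
    quality trimming clips the reverse-read head.
    """
    for a, b in ((keep_remnant, drop_remnant), (drop_remnant, keep_remnant)):
        if a.startswith(b):
            raise ValueError("keep and drop remnants may not share a prefix")
    kept = []
    n_drop_site = n_no_site = n_no_anchor = 0
    for pair in pairs:
        if pair.fwd_seq.startswith(drop_remnant):
            n_drop_site += 1
        elif not pair.fwd_seq.startswith(keep_remnant):
            n_no_site += 1
        elif require_anchor and not pair.rev_seq.startswith(anchor_remnant):
            n_no_anchor += 1
        else:
            kept.append(pair)
    if report is not None:
        report.add(
            "cut_sites", len(pairs), len(kept),
            {"drop_remnant": n_drop_site, "no_site": n_no_site,
             "no_anchor": n_no_anchor},
        )
    return kept


def _internal_hit(seq: str, sites: dict[str, str], excl: list[tuple[int, int]]) -> str | None:
    """Name of the first enzyme whose complete site lies strictly inside
    the read (a match overlapping an expected terminal-remnant window is
    the cut remnant itself, not an internal site)."""
    for enz, site in sites.items():
        start = 0
        while True:
            i = seq.find(site, start)
            if i < 0:
                break
            j = i + len(site)
            if not any(i < e and j > s for s, e in excl):
                return enz
            start = i + 1
    return None


def filter_internal_sites(
    merged: list[MergedRead],
    pairs: list[ReadPair],
    sites: dict[str, str] | None = None,
    fwd_start_remnant: str = MSEI_REMNANT,
    rev_start_remnant: str = ECORI_REMNANT,
    report: FilterReport | None = None,
) -> tuple[list[MergedRead], list[ReadPair]]:
    """Remove reads with a complete internal restriction site.

    An internal site indicates incomplete digestion or chimerism.  The
    expected terminal remnants (MseI at the forward/merged-read start,
    EcoRI remnant at the reverse-read start and, reverse-complemented, at
    the merged-read end) are excluded from the scan.
    """
    if sites is None:
        sites = dict(RECOGNITION_SITES)
    if not sites:
        raise ValueError("site set must be non-empty")
    drops: dict[str, int] = {f"internal_{e}": 0 for e in sites}

    kept_merged = []
    for read in merged:
        n = len(read.seq)
        excl = [(0, len(fwd_start_remnant)), (n - len(rev_start_remnant), n)]
        enz = _internal_hit(read.seq, sites, excl)
        if enz is None:
            kept_merged.append(read)
        else:
            drops[f"internal_{enz}"] += 1

    kept_pairs = []
    for pair in pairs:
        excl_f = [(0, len(fwd_start_remnant))]
        excl_r = [(0, len(rev_start_remnant))] if pair.rev_seq.startswith(rev_start_remnant) else []
        enz = _internal_hit(pair.fwd_seq, sites, excl_f) or _internal_hit(
            pair.rev_seq, sites, excl_r
        )
        if enz is None:
            kept_pairs.append(pair)
        else:
            drops[f"internal_{enz}"] += 1
    if report is not None:
        n_in = len(merged) + len(pairs)
        report.add("internal_sites", n_in, len(kept_merged) + len(kept_pairs), drops)
    return kept_merged, kept_pairs


# ----------------------------------------------------------- full chain
def run_chain(
    pairs: list[ReadPair],
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
    min_overlap: int = 30,
    min_merged_len: int = 240,
    q_min: int = 30,
    max_len: int = 130,
    rev_head_clip: int = 6,
) -> tuple[dict[str, tuple[list[MergedRead], list[ReadPair]]], FilterReport]:
    """Run the full per-sample filter chain and return survivors + report."""
    report = FilterReport()
    by_sample = demultiplex_inline(pairs, barcode_map, max_mismatch, report)
    out: dict[str, tuple[list[MergedRead], list[ReadPair]]] = {}
    for sample, sample_pairs in by_sample.items():
        p = remove_pcr_duplicates(sample_pairs, report=report)
        merged, unmerged = merge_pairs(
            p, min_overlap=min_overlap, min_merged_len=min_merged_len, report=report
        )
        n_in = len(merged) + len(unmerged)
        unmerged = check_cut_sites(unmerged, report=None)
        merged_kept = []
        m_drop = m_nosite = 0
        for m in merged:
            if m.seq.startswith(CVIQI_REMNANT):
                m_drop += 1
            elif not m.seq.startswith(MSEI_REMNANT):
                m_nosite += 1
            else:
                merged_kept.append(m)
        merged = merged_kept
        n_kept = len(merged) + len(unmerged)
        report.add("cut_sites", n_in, n_kept, {"site_fail": n_in - n_kept})
        unmerged = quality_trim(
            unmerged, q_min=q_min, max_len=max_len, rev_head_clip=rev_head_clip,
            report=report,
        )
        merged, unmerged = filter_internal_sites(merged, unmerged, report=report)
        out[sample] = (merged, unmerged)
    return out, report


# ------------------------------------------------------------------ I/O
def _open(path, mode="rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Load paired FASTQ; the i5 tag is read from an ``i5:<tag>`` token in
    the read-header comment (empty when absent)."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = t1.split()[0]
            i5 = ""
            for tok in t1.split()[1:]:
                if tok.startswith("i5:"):
                    i5 = tok[3:]
            pairs.append(ReadPair(rid, s1, q1, s2, q2, i5))
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], r1_path, r2_path) -> None:
    with _open(r1_path, "wt") as f1, _open(r2_path, "wt") as f2:
        for p in pairs:
            header = f"{p.id} i5:{p.i5}"
            f1.write(f"@{header}\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
            f2.write(f"@{header}\n{p.rev_seq}\n+\n{p.rev_qual}\n")
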