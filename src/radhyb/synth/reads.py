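"""Synthetic 3RAD genome, library and raw-read generator.

The genome is a single scrubbed-background chromosome (no spurious
recognition sites) into which EcoRI--MseI digestion fragments are planted
at known coordinates: qualifying fragments inside the size-selection
window, wrong-size decoys, and CviQI-flanked decoys.  The read set adds
library-level artefacts the genome cannot carry: mergeable short inserts,
below-size fragments, CviQI-cut and siteless read starts, incomplete
digestion (internal sites), low-quality mates, corrupted barcodes, and
PCR duplicates (same i5 tag and sequences).  Both a fragment truth table
and a per-pair truth table are returned so every downstream filter stage
can be checked without re-simulation.

Read-pair layout (forward mate sequenced from the MseI end):

    forward = barcode + "TAA" + revcomp(core) + "GAATT"  (truncated to read_len)
    reverse = "AATTC" + core + "TTA"...                  (= revcomp of the insert)

so the insert length equals len(core) + 8 while the corresponding genomic
digestion fragment ("AATTC" + core + "T") is two bases shorter - the
double-counted sticky-end overhang.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..reads3rad import ReadPair, revcomp
from .config import SimConfig

_SITES = ("TTAA", "GAATTC", "GTAC")
_BASES = np.array(list("ACGT"))

#: per-pair category mix of the synthetic library
_CATEGORY_WEIGHTS = {
    "normal": 0.55,
    "mergeable": 0.15,
    "short": 0.08,
    "cviqi": 0.07,
    "nosite": 0.03,
    "internal": 0.06,
    "lowq": 0.03,
    "badbc": 0.03,
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _scrub_sites(seq: str, rng: np.random.Generator) -> str:
    """Destroy every enzyme recognition site by mutating one base."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for site in _SITES:
            i = text.find(site)
            while i >= 0:
                pos = i + len(site) // 2
                cur = s[pos]
                s[pos] = str(rng.choice([b for b in "ACGT" if b != cur]))
                changed = True
                text = "".join(s)
                i = text.find(site, i + 1)
    return "".join(s)


def _scrubbed_core(rng: np.random.Generator, n: int) -> str:
    return _scrub_sites(_random_seq(rng, n), rng)


@dataclass
class SyntheticReadSet:
    genome: dict[str, str]
    fragments: pd.DataFrame  # genome digestion-fragment truth
    pairs: list[ReadPair]
    truth: pd.DataFrame  # per-pair truth

    def write(self, out_dir) -> None:
        import os

        from ..reads3rad import write_fastq_pairs

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "genome.fasta"), "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i: i + 80] + "\n")
        write_fastq_pairs(
            self.pairs,
            os.path.join(out_dir, "reads_R1.fastq"),
            os.path.join(out_dir, "reads_R2.fastq"),
        )
        self.fragments.to_csv(
            os.path.join(out_dir, "fragment_truth.tsv"), sep="\t", index=False
        )
        self.truth.to_csv(os.path.join(out_dir, "read_truth.tsv"), sep="\t", index=False)


def _build_genome(
    rng: np.random.Generator,
    window: tuple[int, int],
    n_qualifying: int,
    n_decoy_size: int,
    n_decoy_cviqi: int,
) -> tuple[str, pd.DataFrame, list[str]]:
    lo, hi = window
    rows = []
    parts = []
    cores_qualifying: list[str] = []
    pos = 0

    def pad() -> None:
        nonlocal pos
        n = int(rng.integers(120, 220))
        parts.append(_scrubbed_core(rng, n))
        pos += n

    plant_specs = (
        [("qualifying", True)] * n_qualifying
        + [("decoy_size", True)] * n_decoy_size
        + [("decoy_cviqi", False)] * n_decoy_cviqi
    )
    rng.shuffle(plant_specs := np.array(plant_specs, dtype=object))

    pad()
    for idx, (kind, mse_end) in enumerate(plant_specs):
        if kind == "qualifying":
            frag_len = int(rng.integers(lo, hi + 1))
        elif kind == "decoy_size":
            frag_len = int(rng.integers(hi + 60, hi + 200)) if rng.random() < 0.5 else int(
                rng.integers(260, lo - 10)
            )
        else:
            frag_len = int(rng.integers(lo, hi + 1))
        core = _scrubbed_core(rng, frag_len - 6)
        right_site = "TTAA" if mse_end else "GTAC"
        plant = "GAATTC" + core + right_site
        # cut points: after G of GAATTC, after the first base of the right site
        start = pos + 1
        end = pos + 6 + len(core) + 1
        rows.append(
            {
                "fragment_id": f"frag{idx:03d}",
                "kind": kind,
                "seqid": "chr1",
                "start": start,
                "end": end,
                "length": end - start,
                "left_enzyme": "EcoRI",
                "right_enzyme": "MseI" if mse_end else "CviQI",
                "qualifies": bool(kind == "qualifying"),
            }
        )
        if kind == "qualifying":
            cores_qualifying.append(core)
        parts.append(plant)
        pos += len(plant)
        pad()
    genome = "".join(parts)
    return genome, pd.DataFrame(rows), cores_qualifying


def _make_pair(
    pair_id: str,
    core: str,
    barcode: str,
    i5: str,
    read_len: int,
    qual_char: str,
    start_remnant: str = "TAA",
    rev_qual_char: str | None = None,
) -> ReadPair:
    insert = start_remnant + revcomp(core) + "GAATT"
    fwd = (barcode + insert)[:read_len]
    rev = revcomp(insert)[:read_len]
    rq = (rev_qual_char or qual_char) * len(rev)
    return ReadPair(pair_id, fwd, qual_char * len(fwd), rev, rq, i5)


def simulate_genome_and_reads(
    config: SimConfig,
    n_pairs: int = 2000,
    n_qualifying: int = 12,
    n_decoy_size: int = 3,
    n_decoy_cviqi: int = 2,
) -> SyntheticReadSet:
    """Generate the genome, the raw paired reads and both truth tables."""
    config.validate()
    rp = config.read_params
    lo, hi = rp.size_window
    if 2 * rp.read_len < 240:
        raise ValueError("size window / merge thresholds unreachable at this read length")

    grng = config.rng("genome")
    genome, fragments, cores = _build_genome(
        grng, rp.size_window, n_qualifying, n_decoy_size, n_decoy_cviqi
    )

    rng = config.rng("reads")
    samples = sorted(rp.barcode_map)
    qual_char = chr(33 + rp.base_quality)
    max_bc = max(len(b) for b in rp.barcode_map.values())
    # insert covered by both mates iff overlap >= 30
    merge_cap = 2 * rp.read_len - max_bc - 30

    cats = list(_CATEGORY_WEIGHTS)
    weights = np.array([_CATEGORY_WEIGHTS[c] for c in cats])
    draws = rng.choice(len(cats), size=n_pairs, p=weights / weights.sum())

    pairs: list[ReadPair] = []
    rows = []
    used_i5: dict[tuple[str, str], set[str]] = {}

    def fresh_i5(group: tuple[str, str]) -> str:
        pool = used_i5.setdefault(group, set())
        while True:
            tag = _random_seq(rng, rp.i5_len)
            if tag not in pool:
                pool.add(tag)
                return tag

    internal_cycle = ("GAATTC", "TTAA", "GTAC")
    for n, ci in enumerate(draws):
        cat = cats[ci]
        sample = samples[n % len(samples)]
        barcode = rp.barcode_map[sample]
        pair_id = f"p{n:05d}"
        internal_enzyme = ""
        barcode_ok = True
        lowq = False
        start_remnant = "TAA"

        if cat == "normal":
            frag_i = int(rng.integers(0, len(cores)))
            core = cores[frag_i]
            fragment_id = f"frag_q{frag_i}"
        else:
            fragment_id = f"ins_{pair_id}"
            if cat == "mergeable":
                core = _scrubbed_core(rng, int(rng.integers(240, merge_cap + 1)) - 8)
            elif cat == "short":
                core = _scrubbed_core(rng, int(rng.integers(180, 236)) - 8)
            elif cat == "cviqi":
                start_remnant = "TAC"
                core = _scrubbed_core(rng, int(rng.integers(lo, hi + 1)) - 8)
            elif cat == "nosite":
                start_remnant = "GGG"
                core = _scrubbed_core(rng, int(rng.integers(lo, hi + 1)) - 8)
            elif cat == "internal":
                site = internal_cycle[n % 3]
                left = _scrubbed_core(rng, 40)
                right = _scrubbed_core(rng, int(rng.integers(lo, hi + 1)) - 48 - len(site))
                core = left + revcomp(site) + right
                internal_enzyme = {"GAATTC": "EcoRI", "TTAA": "MseI", "GTAC": "CviQI"}[site]
            elif cat == "lowq":
                lowq = True
                core = _scrubbed_core(rng, int(rng.integers(lo, hi + 1)) - 8)
            else:  # badbc
                barcode_ok = False
                core = _scrubbed_core(rng, int(rng.integers(lo, hi + 1)) - 8)
                real = list(rp.barcode_map.values())
                while True:
                    cand = _random_seq(rng, len(barcode))
                    dists = [
                        sum(1 for x, y in zip(cand, b[: len(cand)]) if x != y)
                        for b in real
                    ]
                    if min(dists) >= 2:
                        barcode = cand
                        break

        i5 = fresh_i5((sample, fragment_id))
        pair = _make_pair(
            pair_id, core, barcode, i5, rp.read_len, qual_char,
            start_remnant=start_remnant,
            rev_qual_char=chr(33 + 2) if lowq else None,
        )
        pairs.append(pair)
        rows.append(
            {
                "pair_id": pair_id,
                "sample": sample,
                "category": cat,
                "fragment_id": fragment_id,
                "insert_len": len(core) + 8,
                "i5": i5,
                "barcode_ok": barcode_ok,
                "internal_enzyme": internal_enzyme,
                "dup_group": pair_id,
                "dup_rank": 0,
            }
        )

    # PCR duplicates: extra copies with identical i5 and sequences
    n_base = len(pairs)
    for n in range(n_base):
        if rng.random() < rp.duplicate_rate:
            src = pairs[n]
            dup = ReadPair(
                f"{src.id}_dup", src.fwd_seq, src.fwd_qual, src.rev_seq,
                src.rev_qual, src.i5,
            )
            pairs.append(dup)
            row = dict(rows[n])
            row.update({"pair_id": dup.id, "dup_rank": 1})
            rows.append(row)

    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    rows = [rows[i] for i in order]
    # duplicate-removal keeps the first occurrence: re-rank by shuffled order
    first_seen: dict[tuple[str, str], int] = {}
    for rank, row in enumerate(rows):
        key = (row["sample"], row["dup_group"])
        if key not in first_seen:
            first_seen[key] = rank
            row["dup_rank"] = 0
        else:
            row["dup_rank"] = 1

    return SyntheticReadSet(
        {"chr1": genome}, fragments, pairs, pd.DataFrame(rows)
    )
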