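"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates the study design end-to-end so every stage is testable without
the deposited sequencing data: 12 small-RNA libraries (3 replicates x 4
conditions: control_1, drought, control_2, rehydration) with NB-distributed
counts and planted condition effects plus 3' isomiR variants; two
degradome libraries ("ak" control, "as" drought) whose tags pile up at the
canonical cleavage positions of planted miRNA/target pairs; and qPCR Ct
tables consistent with planted target fold changes.

All randomness flows from ``SimulationConfig.seed`` through per-stage
integer-derived streams, so each generator is deterministic under seed
and independent of call order.

The default configuration mirrors the study's scale: 150 conserved
miRNAs across 12 libraries, 49 miRNAs with a drought effect (11 up, 38
down) and 25 with a rehydration effect (9 up, 16 down, overlapping the
drought set in 5 up + 11 down), NB dispersion 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import CONDITIONS, FastqRecord, write_fastq

# The two arms of the miR172b duplex, printed in the study; packaged as
# named simulation fixtures (DNA alphabet).
MIR172B_5P = "GCAGCACCACCAAGATTCACA"
MIR172B_3P = "AGAATCTTGATGATGCTGCAT"

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Per-stage RNG stream tags (mixed with the seed).
_STAGE_SRNA, _STAGE_DEGRADOME, _STAGE_CT, _STAGE_SETUP = 1, 2, 3, 4


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, stage]))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_mirnas: int = 150
    n_background_seqs: int = 300
    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (300, 800)
    planted_effects: list[tuple[int, str, float]] | None = None  # (mirna_idx, contrast, log2fc)
    dispersion: float = 0.1
    mean_count_range: tuple[float, float] = (20.0, 1000.0)
    isomir_rate: float = 0.1
    degradome_peak_fraction: float = 0.5
    degradome_background_tags: int = 2000
    degradome_site_tags: int = 200
    ct_noise_sd: float = 0.2
    include_mir172: bool = True

    def __post_init__(self):
        for lo, hi in (self.transcript_len_range, self.mean_count_range):
            if lo > hi:
                raise ValueError("range bounds must be ordered (min <= max)")
        for frac in (self.isomir_rate, self.degradome_peak_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(self.n_mirnas, self.seed)


def default_planted_effects(n_mirnas: int, seed: int = 0) -> list[tuple[int, str, float]]:
    """Planted effects mirroring the study's differential counts.

    11 drought-up and 38 drought-down; 9 rehydration-up and 16
    rehydration-down, of which 5 up and 11 down are common with drought.
    Effect magnitudes are drawn once (seeded) from the printed table's
    typical range, 1.0-2.5 in absolute log2 units. Scaled down
    proportionally when ``n_mirnas`` is too small for the full design.
    """
    rng = _rng(seed, _STAGE_SETUP)

    def mag(n, sign):
        return sign * rng.uniform(1.0, 2.5, n)

    scale = min(1.0, n_mirnas / 58.0)
    n_up_d, n_down_d = max(1, round(11 * scale)), max(1, round(38 * scale))
    if n_up_d + n_down_d > n_mirnas:
        raise ValueError("n_mirnas too small for the default planted design")
    n_common_up, n_common_down = round(5 * scale), round(11 * scale)
    # rehydration-only effects use miRNAs beyond the drought set; trim to fit
    room = n_mirnas - n_up_d - n_down_d
    n_new_up_r = min(max(1, round(4 * scale)), room)
    n_new_down_r = min(max(1, round(5 * scale)), room - n_new_up_r)

    effects: list[tuple[int, str, float]] = []
    up_d = list(range(n_up_d))
    down_d = list(range(n_up_d, n_up_d + n_down_d))
    for i, m in zip(up_d, mag(len(up_d), +1)):
        effects.append((i, "drought", float(m)))
    for i, m in zip(down_d, mag(len(down_d), -1)):
        effects.append((i, "drought", float(m)))
    common_up = up_d[:n_common_up]
    common_down = down_d[:n_common_down]
    start_new = n_up_d + n_down_d
    new_up = list(range(start_new, start_new + n_new_up_r))
    new_down = list(range(start_new + n_new_up_r, start_new + n_new_up_r + n_new_down_r))
    for i, m in zip(common_up + new_up, mag(n_common_up + len(new_up), +1)):
        effects.append((i, "rehydration", float(m)))
    for i, m in zip(common_down + new_down, mag(n_common_down + len(new_down), -1)):
        effects.append((i, "rehydration", float(m)))
    if any(i >= n_mirnas for i, _, _ in effects):
        raise ValueError("n_mirnas too small for the default planted design")
    return effects


@dataclass(frozen=True)
class PlantedTarget:
    mirna_name: str
    transcript_id: str
    site_start: int  # 1-based
    cleavage_position: int  # 1-based, opposite miRNA position 10


@dataclass
class GroundTruth:
    mature_set: dict[str, str]
    planted_calls: dict[str, dict[str, str]]  # mirna -> contrast -> call
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_fcs: dict[str, float] = field(default_factory=dict)  # gene -> drought FC

    def calls_for(self, contrast: str) -> pd.Series:
        return pd.Series(
            {m: calls.get(contrast, "unchanged") for m, calls in self.planted_calls.items()},
            name="call",
        )


def _random_kmers(rng: np.random.Generator, n: int, length_choices, existing: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        L = int(rng.choice(length_choices))
        seq = "".join(rng.choice(_BASES, L))
        if seq not in existing:
            existing.add(seq)
            out.append(seq)
    return out


def make_mature_set(config: SimulationConfig) -> dict[str, str]:
    """Random 21-nt mature miRNA reference; the first two entries are the
    printed miR172b arms when ``include_mir172`` is set."""
    rng = _rng(config.seed, _STAGE_SETUP)
    mature: dict[str, str] = {}
    existing: set[str] = set()
    if config.include_mir172 and config.n_mirnas >= 2:
        mature["hvu-miR172b-5p"] = MIR172B_5P
        mature["hvu-miR172b-3p"] = MIR172B_3P
        existing.update(mature.values())
    n_random = config.n_mirnas - len(mature)
    for i, seq in enumerate(_random_kmers(rng, n_random, [21], existing)):
        mature[f"sim-miR{i + 1:03d}"] = seq
    return mature


def default_sample_sheet() -> pd.DataFrame:
    """The study's 3 x 4 design: 12 libraries, 3 replicates per condition."""
    rows = [
        {"library_id": f"{cond}_r{rep}", "condition": cond, "replicate": rep}
        for cond in CONDITIONS
        for rep in (1, 2, 3)
    ]
    return pd.DataFrame(rows)


@dataclass
class SrnaSimulation:
    reads: dict[str, list[str]]  # library_id -> trimmed read sequences
    sample_sheet: pd.DataFrame
    ground_truth: GroundTruth


def _call(log2fc: float, fc_threshold: float = 0.6) -> str:
    if log2fc >= fc_threshold:
        return "up"
    if log2fc <= -fc_threshold:
        return "down"
    return "unchanged"


def simulate_srna_libraries(
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> SrnaSimulation:
    """Generate the 12 small-RNA libraries.

    Per library, each mature miRNA's read count is NB(mean * 2^effect,
    dispersion) where the effect applies only in the contrast's treated
    condition; a fraction ``isomir_rate`` of each miRNA's reads are
    emitted as +/-1-2 nt 3' variants, the rest as the exact mature
    sequence. Background sequences (20-24 nt) are added at low means.
    With ``outdir`` set, one FASTQ per library plus the sample sheet are
    written (byte-identical under a fixed seed).
    """
    rng = _rng(config.seed, _STAGE_SRNA)
    mature = make_mature_set(config)
    names = list(mature)
    sheet = default_sample_sheet()

    base_mean = np.exp(
        rng.uniform(np.log(config.mean_count_range[0]), np.log(config.mean_count_range[1]), len(names))
    )
    existing = set(mature.values())
    background = _random_kmers(rng, config.n_background_seqs, [20, 21, 22, 23, 24], existing)
    bg_mean = rng.uniform(1.0, 15.0, len(background))

    effect = {}  # (mirna_name, condition) -> log2fc
    planted_calls: dict[str, dict[str, str]] = {n: {} for n in names}
    for idx, contrast, lfc in config.planted_effects:
        treated = "drought" if contrast == "drought" else "rehydration"
        effect[(names[idx], treated)] = lfc
        planted_calls[names[idx]][contrast] = _call(lfc)

    nb_n = 1.0 / config.dispersion

    def nb_draw(mu: np.ndarray) -> np.ndarray:
        return rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    reads: dict[str, list[str]] = {}
    for _, row in sheet.iterrows():
        lib, cond = row["library_id"], row["condition"]
        lib_reads: list[str] = []
        mu = base_mean * np.array([2.0 ** effect.get((n, cond), 0.0) for n in names])
        counts = nb_draw(mu)
        for name, count in zip(names, counts):
            if count == 0:
                continue
            n_iso = rng.binomial(count, config.isomir_rate)
            lib_reads.extend([mature[name]] * int(count - n_iso))
            for _ in range(int(n_iso)):
                lib_reads.append(_isomir_variant(rng, mature[name]))
        for seq, count in zip(background, nb_draw(bg_mean)):
            lib_reads.extend([seq] * int(count))
        reads[lib] = lib_reads

    sim = SrnaSimulation(reads, sheet, GroundTruth(mature, planted_calls))
    if outdir is not None:
        _write_srna(sim, Path(outdir))
    return sim


def _isomir_variant(rng: np.random.Generator, mature: str) -> str:
    """A 3' length variant of the mature sequence: trim or extend 1-2 nt."""
    shift = int(rng.choice([-2, -1, 1, 2]))
    if shift < 0:
        return mature[:shift]
    return mature + "".join(rng.choice(_BASES, shift))


def _write_srna(sim: SrnaSimulation, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    from .formats import write_sample_sheet

    write_sample_sheet(sim.sample_sheet, outdir / "sample_sheet.tsv")
    for lib, seqs in sim.reads.items():
        records = (
            FastqRecord(f"{lib}_read{i}", seq, "I" * len(seq)) for i, seq in enumerate(seqs)
        )
        write_fastq(records, outdir / f"{lib}.fastq")


@dataclass
class DegradomeSimulation:
    tags: dict[str, list[str]]  # "ak" (control) and "as" (drought)
    transcripts: dict[str, str]
    ground_truth: GroundTruth


TAG_LENGTH = 20  # post-trim PARE tag length; comfortably above the 14-nt floor


def simulate_degradome(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    outdir: str | Path | None = None,
) -> DegradomeSimulation:
    """Generate the two degradome libraries and the transcript set.

    One planted target site per transcript, for the miRNAs with planted
    effects first (then the remaining miRNAs): the transcript carries the
    exact reverse complement of the miRNA, and ``ground_truth`` is
    updated with the site and its canonical cleavage coordinate. Per
    planted target, ``degradome_site_tags`` tags are emitted of which a
    fraction ``degradome_peak_fraction`` start exactly at the cleavage
    position and the rest start uniformly along the transcript; in the
    drought library ("as") the peak intensity is scaled by 2^(miRNA
    drought log2fc), so cleavage strength tracks miRNA abundance.
    Background tags are uniform over random transcripts in both
    libraries. All tags are sense-strand copies of length 20.
    """
    rng = _rng(config.seed, _STAGE_DEGRADOME)
    names = list(ground_truth.mature_set)
    with_effect = [n for n in names if "drought" in ground_truth.planted_calls.get(n, {})]
    rest = [n for n in names if n not in set(with_effect)]
    chosen = (with_effect + rest)[: config.n_transcripts]

    transcripts: dict[str, str] = {}
    ground_truth.planted_targets = []
    lo, hi = config.transcript_len_range
    for k, name in enumerate(chosen):
        tid = f"TX{k + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_BASES, length))
        site = reverse_complement(ground_truth.mature_set[name])
        L = len(site)
        # keep the site away from the edges so tags around it fit
        start0 = int(rng.integers(TAG_LENGTH, length - L - TAG_LENGTH))
        seq = seq[:start0] + site + seq[start0 + L :]
        transcripts[tid] = seq
        cleavage = start0 + 1 + (L - 10)  # transcript base opposite miRNA position 10
        ground_truth.planted_targets.append(PlantedTarget(name, tid, start0 + 1, cleavage))

    def tag_at(tid: str, pos1: int) -> str | None:
        seq = transcripts[tid]
        tag = seq[pos1 - 1 : pos1 - 1 + TAG_LENGTH]
        return tag if len(tag) == TAG_LENGTH else None

    tags: dict[str, list[str]] = {"ak": [], "as": []}
    for target in ground_truth.planted_targets:
        drought_lfc = 0.0
        calls = ground_truth.planted_calls.get(target.mirna_name, {})
        if "drought" in calls:
            for idx, contrast, lfc in config.planted_effects:
                if names[idx] == target.mirna_name and contrast == "drought":
                    drought_lfc = lfc
                    break
        for lib, scale in (("ak", 1.0), ("as", 2.0**drought_lfc)):
            n_tags = max(1, int(round(config.degradome_site_tags * scale)))
            n_peak = int(rng.binomial(n_tags, config.degradome_peak_fraction))
            peak_tag = tag_at(target.transcript_id, target.cleavage_position)
            if peak_tag:
                tags[lib].extend([peak_tag] * n_peak)
            length = len(transcripts[target.transcript_id])
            for pos1 in rng.integers(1, length - TAG_LENGTH + 2, n_tags - n_peak):
                t = tag_at(target.transcript_id, int(pos1))
                if t:
                    tags[lib].append(t)

    tids = list(transcripts)
    for lib in tags:
        for _ in range(config.degradome_background_tags):
            tid = tids[int(rng.integers(len(tids)))]
            length = len(transcripts[tid])
            t = tag_at(tid, int(rng.integers(1, length - TAG_LENGTH + 2)))
            if t:
                tags[lib].append(t)

    sim = DegradomeSimulation(tags, transcripts, ground_truth)
    if outdir is not None:
        _write_degradome(sim, Path(outdir))
    return sim


def _write_degradome(sim: DegradomeSimulation, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    from .formats import write_fasta

    write_fasta(sim.transcripts, outdir / "transcripts.fasta")
    for lib, seqs in sim.tags.items():
        records = (
            FastqRecord(f"{lib}_tag{i}", seq, "I" * len(seq)) for i, seq in enumerate(seqs)
        )
        write_fastq(records, outdir / f"degradome_{lib}.fastq")


REFERENCE_GENE = "ARF1-like"  # ADP-ribosylation factor 1-like internal reference
_REFERENCE_CT = 20.0
_TARGET_BASE_CT = 24.0


def simulate_ct_tables(
    config: SimulationConfig,
    ground_truth: GroundTruth,
    genes: dict[str, float] | None = None,
    outpath: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a qPCR Ct table consistent with planted fold changes.

    ``genes`` maps gene name -> planted drought fold change (FC > 0 on
    the raw 2^-ddCt scale); when omitted, one gene per planted degradome
    target is created with FC anticorrelated to the miRNA's drought
    effect (target FC = 2^(-log2fc) of its miRNA). Reference-gene Ct is
    constant plus Gaussian noise; target Ct in the treated condition is
    shifted by -log2(FC). Three replicates per condition, matching the
    study layout.
    """
    rng = _rng(config.seed, _STAGE_CT)
    sheet = default_sample_sheet()
    if genes is None:
        genes = {}
        names = list(ground_truth.mature_set)
        lfc_by_name = {}
        for idx, contrast, lfc in config.planted_effects:
            if contrast == "drought":
                lfc_by_name[names[idx]] = lfc
        for target in ground_truth.planted_targets:
            lfc = lfc_by_name.get(target.mirna_name)
            if lfc is not None:
                genes[f"target_of_{target.mirna_name}"] = float(2.0**-lfc)
    ground_truth.planted_fcs = dict(genes)

    rows = []
    for _, lib_row in sheet.iterrows():
        lib, cond = lib_row["library_id"], lib_row["condition"]
        rows.append(
            {
                "gene": REFERENCE_GENE,
                "library_id": lib,
                "ct": _REFERENCE_CT + rng.normal(0.0, config.ct_noise_sd),
                "is_reference": True,
            }
        )
        for gene, fc in genes.items():
            ct = _TARGET_BASE_CT
            if cond == "drought":
                ct -= np.log2(fc)
            rows.append(
                {
                    "gene": gene,
                    "library_id": lib,
                    "ct": ct + rng.normal(0.0, config.ct_noise_sd),
                    "is_reference": False,
                }
            )
    table = pd.DataFrame(rows)
    if outpath is not None:
        table.to_csv(outpath, sep="\t", index=False)
    return table
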