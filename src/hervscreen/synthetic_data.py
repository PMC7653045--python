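"""Synthetic inputs with known ground truth for the whole pipeline.

The study's raw data are not deposited in machine-readable form, so every
input the pipeline consumes can be generated here with a planted truth:
HERV-like transcripts with controllable open reading frames, a deterministic
stand-in for an MHC binding-rank predictor calibrated to a target binder
rate, a three-class cohort (healthy donors, patients pre- and post-AZA) with
HLA-restricted per-peptide response truth, negative-binomial barcode counts
with planted enrichment, and log-normal TPM matrices with a disease effect.

All generators are byte-deterministic for a fixed seed.  The default cohort
structure mirrors the screening study (27 healthy donors, 34 patients, the
four most common Caucasian HLA class I alleles); the per-class response
probabilities are synthetic choices, not estimates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .barcode_enrichment import CountsTable
from .peptide_library import (
    HervTranscript,
    PeptideRecord,
    RankProvider,
    build_library,
    write_library_tsv,
)

__all__ = [
    "SimulationConfig",
    "gen_herv_transcripts",
    "gen_rank_provider",
    "gen_cohort",
    "gen_barcode_counts",
    "gen_expression",
    "simulate_all",
    "write_transcript_fasta",
    "nb_counts",
]

DEFAULT_HLA_POOL = (
    "HLA-A*01:01",
    "HLA-A*02:01",
    "HLA-B*07:02",
    "HLA-B*08:01",
)

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort."""

    seed: int = 0
    n_loci: int = 30
    transcript_length_range: tuple[int, int] = (400, 2500)
    orf_fraction: float = 0.85
    binder_rate: float = 0.019
    n_healthy: int = 27
    n_pre: int = 34
    n_post: int = 34
    hla_pool: tuple[str, ...] = DEFAULT_HLA_POOL
    response_prob_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": 0.002, "pre": 0.010, "post": 0.012}
    )
    post_gain_prob: float = 0.0
    post_loss_prob: float = 0.0
    enrichment_fold: float = 50.0
    baseline_depth: float = 100.0
    nb_dispersion: float = 0.1
    tpm_disease_effect: float = 2.0
    tpm_noise_sd: float = 0.5
    tpm_post_shift_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.transcript_length_range
        if lo < 60 or hi < lo:
            raise ConfigurationError(
                f"invalid transcript length range {self.transcript_length_range}"
            )
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if not 0.0 < self.binder_rate < 1.0:
            raise ConfigurationError("binder_rate must lie in (0, 1)")
        if self.enrichment_fold < 1.0:
            raise ConfigurationError("enrichment_fold must be >= 1")
        if self.nb_dispersion <= 0 or self.baseline_depth <= 0:
            raise ConfigurationError("dispersion and depth must be positive")
        probs = list(self.response_prob_by_class.values()) + [
            self.orf_fraction,
            self.post_gain_prob,
            self.post_loss_prob,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("all probabilities must lie in [0, 1]")
        if not 1 <= len(self.hla_pool):
            raise ConfigurationError("hla_pool must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("transcript_length_range", "hla_pool"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# Transcripts

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _scrub_atg(seq: str) -> str:
    """Remove every ATG occurrence (so no ORF can start)."""
    while "ATG" in seq:
        i = seq.index("ATG")
        seq = seq[: i + 2] + "C" + seq[i + 3 :]
    return seq


def gen_herv_transcripts(cfg: SimulationConfig) -> list[HervTranscript]:
    """Generate transcripts; ``orf_fraction`` of the loci carry a planted ORF
    (ATG + >= 11 codons + stop) so 9-11mers exist, the rest lack any ATG and
    translate to nothing.  Loci may own 1-3 transcripts sharing the same ORF
    with different flanks, exercising same-locus deduplication downstream."""
    rng = _rng(cfg, 1)
    lo, hi = cfg.transcript_length_range
    n_orf = int(round(cfg.orf_fraction * cfg.n_loci))
    out: list[HervTranscript] = []
    for i in range(cfg.n_loci):
        locus = f"ERVSIM-{i + 1}"
        has_orf = i < n_orf
        n_tx = int(rng.integers(1, 4))
        orf_block = ""
        if has_orf:
            aa_len = int(rng.integers(12, 61))
            codons = rng.choice(_NON_STOP_CODONS, size=aa_len)
            stop = _STOPS[int(rng.integers(0, 3))]
            orf_block = "ATG" + "".join(codons) + stop
        for t in range(n_tx):
            length = int(rng.integers(lo, hi + 1))
            if has_orf:
                length = max(length, len(orf_block) + 40)
                prefix_len = int(rng.integers(10, length - len(orf_block) - 9))
                suffix_len = length - len(orf_block) - prefix_len
                prefix = _scrub_atg(_random_seq(rng, prefix_len))
                suffix = _random_seq(rng, suffix_len)
                seq = prefix + orf_block + suffix
            else:
                seq = _scrub_atg(_random_seq(rng, length))
            out.append(
                HervTranscript(
                    locus_name=locus, accession=f"SIM{i + 1:03d}.{t + 1}", sequence=seq
                )
            )
    return out


def write_transcript_fasta(
    transcripts: Iterable[HervTranscript], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.locus_name}|{tx.accession}\n")
            for i in range(0, len(tx.sequence), 70):
                fh.write(tx.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Rank provider

def gen_rank_provider(cfg: SimulationConfig) -> RankProvider:
    """Deterministic stand-in for an MHC binding-rank predictor.

    Each (peptide, allele) gets a percentile rank in (0, 100] derived from a
    stable hash of the query and the seed, calibrated so the marginal
    probability of rank <= 2 equals ``binder_rate``.  Peptides containing
    non-standard residues get the sentinel rank 100 (never a binder)."""
    if not 0.0 < cfg.binder_rate < 1.0:
        raise ConfigurationError("binder_rate must lie in (0, 1)")
    rate = cfg.binder_rate
    salt = str(cfg.seed)

    def provider(peptide: str, allele: str) -> float:
        if not set(peptide) <= _AA20:
            return 100.0
        digest = hashlib.sha256(f"{salt}|{peptide}|{allele}".encode()).digest()
        u = (int.from_bytes(digest[:8], "big") + 1) / 2.0**64  # in (0, 1]
        if u <= rate:
            return (u / rate) * 2.0
        return 2.0 + (u - rate) / (1.0 - rate) * 98.0

    return provider


# ---------------------------------------------------------------------------
# Cohort

def gen_cohort(
    cfg: SimulationConfig, pairs: Sequence[tuple[str, str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a sample sheet and the true responder table.

    ``pairs`` is the (peptide, allele) library.  Healthy donors contribute
    one sample; patients paired pre/post samples sharing one truth (with an
    optional post-only gain/loss).  True recognition of a peptide is
    Bernoulli with the class probability, restricted to peptides presented by
    an allele the individual carries.  Truth rows are (individual, class)."""
    rng = _rng(cfg, 2)
    probs = cfg.response_prob_by_class
    n_patients = max(cfg.n_pre, cfg.n_post)
    alleles_arr = np.array(cfg.hla_pool)
    columns = pd.MultiIndex.from_tuples(pairs, names=["peptide", "allele"])
    pair_alleles = np.array([a for _, a in pairs])

    sheet_rows = []
    truth_rows: dict[tuple[str, str], np.ndarray] = {}

    def draw_alleles() -> set[str]:
        k = int(rng.integers(1, min(4, len(alleles_arr)) + 1))
        return set(rng.choice(alleles_arr, size=k, replace=False))

    def draw_truth(p: float, carried: set[str]) -> np.ndarray:
        matched = np.isin(pair_alleles, list(carried))
        return (rng.random(len(pairs)) < p) & matched

    for i in range(cfg.n_healthy):
        ind = f"HD{i + 1:02d}"
        carried = draw_alleles()
        sheet_rows.append(
            {
                "sample_id": f"{ind}_screen",
                "individual_id": ind,
                "class_": "healthy",
                "timepoint": "screen",
                "alleles": ";".join(sorted(carried)),
                "outcome": "NA",
            }
        )
        truth_rows[(ind, "healthy")] = draw_truth(probs["healthy"], carried)

    for i in range(n_patients):
        ind = f"PT{i + 1:02d}"
        carried = draw_alleles()
        outcome = "responder" if rng.random() < 0.5 else "non-responder"
        has_pre = i < cfg.n_pre
        has_post = i < cfg.n_post
        base_p = probs["pre"] if has_pre else probs["post"]
        base = draw_truth(base_p, carried)
        matched = np.isin(pair_alleles, sorted(carried))
        if has_pre:
            sheet_rows.append(
                {
                    "sample_id": f"{ind}_pre",
                    "individual_id": ind,
                    "class_": "pre",
                    "timepoint": "baseline",
                    "alleles": ";".join(sorted(carried)),
                    "outcome": outcome,
                }
            )
            truth_rows[(ind, "pre")] = base
        if has_post:
            post = base.copy()
            if cfg.post_gain_prob > 0:
                gains = (rng.random(len(pairs)) < cfg.post_gain_prob) & matched & ~base
                post |= gains
            if cfg.post_loss_prob > 0:
                losses = (rng.random(len(pairs)) < cfg.post_loss_prob) & base
                post &= ~losses
            sheet_rows.append(
                {
                    "sample_id": f"{ind}_post",
                    "individual_id": ind,
                    "class_": "post",
                    "timepoint": "cycle6",
                    "alleles": ";".join(sorted(carried)),
                    "outcome": outcome,
                }
            )
            truth_rows[(ind, "post")] = post

    sheet = pd.DataFrame(sheet_rows)
    truth = pd.DataFrame(
        np.array(list(truth_rows.values()), dtype=bool),
        index=pd.MultiIndex.from_tuples(truth_rows, names=["individual_id", "class_"]),
        columns=columns,
    )
    return sheet, truth


# ---------------------------------------------------------------------------
# Barcode counts

def nb_counts(
    rng: np.random.Generator, mean, dispersion: float, size=None
) -> np.ndarray:
    """NB counts in the variance = mu + dispersion * mu^2 parametrization."""
    r = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_barcode_counts(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    library: Sequence[PeptideRecord] | Sequence[tuple[str, str]],
    sample_sheet: pd.DataFrame,
) -> tuple[CountsTable, pd.DataFrame]:
    """Generate barcode counts plus the barcode->pMHC annotation table.

    Every sorted sample gets three baseline replicate columns drawn from
    NB(baseline_depth, nb_dispersion); its own column draws non-responders
    from that same null and true responders from NB(enrichment_fold x
    baseline_depth).  Barcodes out of the sample's HLA-matched panel get
    zero counts throughout."""
    if cfg.enrichment_fold < 1.0:
        raise ConfigurationError("enrichment_fold must be >= 1")
    rng = _rng(cfg, 3)
    if library and isinstance(library[0], PeptideRecord):
        pairs = [(r.peptide, r.allele) for r in library]
        loci = {(r.peptide, r.allele): ";".join(sorted(r.source_loci)) for r in library}
    else:
        pairs = list(library)
        loci = {p: "" for p in pairs}
    truth_pairs = set(truth.columns)
    if truth_pairs != set(pairs):
        raise ValueError("truth and library must refer to the same peptide set")

    barcodes = [f"BC{i + 1:04d}" for i in range(len(pairs))]
    annotation = pd.DataFrame(
        {
            "peptide": [p for p, _ in pairs],
            "allele": [a for _, a in pairs],
            "antigen_class": "HERV",
            "source_loci": [loci[p] for p in pairs],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    pair_alleles = np.array([a for _, a in pairs])

    sheet = sample_sheet.set_index("sample_id")
    columns: dict[str, np.ndarray] = {}
    experiments: dict[str, list[str]] = {}
    for sample_id, row in sheet.iterrows():
        carried = {a for a in str(row["alleles"]).split(";") if a}
        in_panel = np.isin(pair_alleles, sorted(carried))
        base_cols = [f"{sample_id}_baseline_{k}" for k in (1, 2, 3)]
        for col in base_cols:
            counts = np.zeros(len(pairs), dtype=int)
            counts[in_panel] = nb_counts(
                rng, cfg.baseline_depth, cfg.nb_dispersion, size=int(in_panel.sum())
            )
            columns[col] = counts
        resp = truth.loc[(row["individual_id"], row["class_"])].to_numpy(bool)
        mean = np.where(
            resp, cfg.enrichment_fold * cfg.baseline_depth, cfg.baseline_depth
        )
        counts = np.zeros(len(pairs), dtype=int)
        counts[in_panel] = nb_counts(
            rng, mean[in_panel], cfg.nb_dispersion, size=int(in_panel.sum())
        )
        columns[sample_id] = counts
        experiments[sample_id] = base_cols

    counts_df = pd.DataFrame(columns, index=pd.Index(barcodes, name="barcode"))
    return CountsTable(counts=counts_df, experiments=experiments), annotation


# ---------------------------------------------------------------------------
# Expression

def gen_expression(
    cfg: SimulationConfig, immunogenic_flags: Mapping[str, bool] | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal TPM matrix (loci x samples) plus its sample sheet.

    Disease-upregulated (flagged) loci are shifted by ``tpm_disease_effect``
    log2 units in patient columns; ``tpm_post_shift_sd`` adds an optional
    per-patient heterogeneous post-treatment shift.  All values are strictly
    positive."""
    rng = _rng(cfg, 4)
    flags = pd.Series(immunogenic_flags).astype(bool)
    loci = list(flags.index)
    up = flags.to_numpy()
    base = rng.normal(0.5, 1.0, size=len(loci))

    columns: dict[str, np.ndarray] = {}
    rows = []

    def add(sample_id: str, ind: str, cls: str, shift: np.ndarray) -> None:
        noise = rng.normal(0.0, cfg.tpm_noise_sd, size=len(loci))
        columns[sample_id] = 2.0 ** (base + shift + noise)
        rows.append(
            {
                "sample_id": sample_id,
                "individual_id": ind,
                "class_": cls,
                "timepoint": cls,
                "alleles": "",
                "outcome": "NA",
            }
        )

    zero = np.zeros(len(loci))
    disease = np.where(up, cfg.tpm_disease_effect, 0.0)
    for i in range(cfg.n_healthy):
        add(f"EHD{i + 1:02d}_rna", f"EHD{i + 1:02d}", "healthy", zero)
    for i in range(cfg.n_pre):
        ind = f"EPT{i + 1:02d}"
        add(f"{ind}_pre_rna", ind, "pre", disease)
        post_shift = disease + np.where(
            up, rng.normal(0.0, cfg.tpm_post_shift_sd), 0.0
        ) if cfg.tpm_post_shift_sd > 0 else disease
        add(f"{ind}_post_rna", ind, "post", post_shift)

    tpm = pd.DataFrame(columns, index=pd.Index(loci, name="locus"))
    return tpm, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration

def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input to ``outdir``.

    Returns a name -> path map of the written files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts = gen_herv_transcripts(cfg)
    provider = gen_rank_provider(cfg)
    library = build_library(transcripts, provider, list(cfg.hla_pool))
    pairs = [(r.peptide, r.allele) for r in library]
    sheet, truth = gen_cohort(cfg, pairs)
    table, annotation = gen_barcode_counts(cfg, truth, library, sheet)

    # loci flagged immunogenic when any of their peptides is truly recognized
    # in a patient row
    patient_truth = truth[truth.index.get_level_values("class_") != "healthy"]
    locus_flags: dict[str, bool] = {}
    loci_by_pep = {r.peptide: r.source_loci for r in library}
    for tx in transcripts:
        locus_flags.setdefault(tx.locus_name, False)
    for pair in truth.columns:
        if bool(patient_truth[pair].any()):
            for locus in loci_by_pep.get(pair[0], frozenset()):
                locus_flags[locus] = True
    tpm, expr_sheet = gen_expression(cfg, pd.Series(locus_flags))

    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "library": outdir / "library.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "truth": outdir / "truth.tsv",
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "tpm": outdir / "tpm.tsv",
        "expression_samples": outdir / "expression_samples.csv",
    }
    write_transcript_fasta(transcripts, paths["transcripts"])
    write_library_tsv(library, paths["library"])
    sheet.to_csv(paths["sample_sheet"], index=False)
    flat_truth = truth.copy()
    flat_truth.columns = [f"{p}|{a}" for p, a in flat_truth.columns]
    flat_truth.to_csv(paths["truth"], sep="\t")
    table.to_tsv(paths["counts"])
    annotation.to_csv(paths["annotation"], sep="\t")
    tpm.to_csv(paths["tpm"], sep="\t")
    expr_sheet.to_csv(paths["expression_samples"], index=False)
    return paths
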