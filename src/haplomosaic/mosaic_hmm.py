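"""Subspecific-origin and heterozygosity mosaics via Viterbi HMMs.

Classical laboratory mouse genomes are mosaics of intervals inherited from
three subspecies (*M. m. domesticus*, *M. m. musculus*, *M. m. castaneus*).
The local origin of each strain is inferred from *diagnostic SNPs*: markers
whose allele, among a labeled reference panel of wild and wild-derived
strains of known subspecies, occurs only within one subspecies.  A
diagnostic allele carried by *every* labeled strain of its subspecies is
fully informative (weight 1); one carried by only some is partially
informative and down-weighted.

A three-state HMM walks the diagnostic markers of a strain.  Emissions
reward carrying the current state's diagnostic allele with
``weight * log(1 - epsilon)`` and penalize carrying another subspecies'
allele with ``weight * log(epsilon / 2)``; heterozygous, missing and
non-diagnostic calls are uninformative (log-emission 0, realizing the
weight as a log-linear exponent on the likelihood).  Transitions cost
``log(rho)`` per switch against ``log(1 - (k-1) * rho)`` to stay, so with
the default ``rho = 1e-6`` a single fully-informative contrary SNP cannot
trigger a switch (the switch round trip costs ~27.6 nats against an
emission gain of ~6.6).  The Viterbi path is compressed to labeled
intervals whose boundaries sit at the midpoint between flanking diagnostic
markers of different states; chromosome ends close at the first/last
diagnostic marker.

Heterozygosity blocks use the same machinery with two states (inbred,
heterozygous) and Bernoulli emissions on the het/hom call at every marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_model import HET, MISSING, GenomicInterval, GenotypeMatrix

SUBSPECIES: tuple[str, str, str] = ("domesticus", "musculus", "castaneus")
HET_STATES: tuple[str, str] = ("inbred", "heterozygous")


@dataclass(frozen=True)
class HmmParams:
    """Tunable HMM parameters.

    epsilon
        emission error rate: probability a diagnostic call contradicts the
        true local origin.
    rho
        per-marker-step switch probability between states.
    partial_weight
        emission weight of partially informative diagnostic SNPs.
    het_emit / het_err
        probability of a heterozygous call in the heterozygous / inbred
        state.
    """

    epsilon: float = 0.05
    rho: float = 1e-6
    partial_weight: float = 0.5
    het_emit: float = 0.5
    het_err: float = 0.01

    def __post_init__(self) -> None:
        for name in ("epsilon", "rho", "partial_weight", "het_emit", "het_err"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if 1.0 - 2.0 * self.rho <= 0.0:
            raise ValueError("rho too large: 1 - 2*rho must stay positive")


@dataclass(frozen=True)
class DiagnosticSNP:
    """A marker allele confined to one subspecies in the labeled panel."""

    marker_index: int
    subspecies: str
    diagnostic_allele: int
    informativeness: str  # "full" | "partial"
    weight: float

    def __post_init__(self) -> None:
        if self.subspecies not in SUBSPECIES:
            raise ValueError(f"unknown subspecies {self.subspecies!r}")
        if self.informativeness not in ("full", "partial"):
            raise ValueError("informativeness must be 'full' or 'partial'")
        if (self.weight == 1.0) != (self.informativeness == "full"):
            raise ValueError("weight 1.0 iff fully informative")


@dataclass(frozen=True)
class MosaicInterval:
    """A labeled genomic segment of one strain's mosaic."""

    strain: str
    bounds: GenomicInterval
    label: str
    mean_posterior_proxy: float


def call_diagnostic_snps(matrix: GenotypeMatrix,
                         labels: dict[str, str],
                         partial_weight: float = 0.5) -> list[DiagnosticSNP]:
    """Diagnostic status of every marker allele from the labeled panel.

    An allele is diagnostic for subspecies S when its homozygous carriers
    among labeled strains are non-empty and all belong to S: fully
    informative if every labeled strain of S carries it, else partial.
    Alleles spanning two or more subspecies, or carried by no labeled
    strain, are not diagnostic.
    """
    if not 0.0 < partial_weight <= 1.0:
        raise ValueError(f"partial_weight must be in (0,1], got {partial_weight}")
    by_subspecies: dict[str, list[int]] = {s: [] for s in SUBSPECIES}
    for strain, sub in labels.items():
        if sub not in SUBSPECIES:
            raise ValueError(f"unknown subspecies label {sub!r} for {strain!r}")
        by_subspecies[sub].append(matrix.strain_index(strain))
    for sub, idx in by_subspecies.items():
        if not idx:
            raise ValueError(f"no labeled strains for subspecies {sub!r}")
    out: list[DiagnosticSNP] = []
    for j in range(matrix.n_markers):
        col = matrix.calls[:, j]
        for allele in (0, 1):
            carrier_subs = [s for s in SUBSPECIES
                            if any(col[i] == allele for i in by_subspecies[s])]
            if len(carrier_subs) != 1:
                continue
            s = carrier_subs[0]
            full = all(col[i] == allele for i in by_subspecies[s])
            out.append(DiagnosticSNP(
                marker_index=j, subspecies=s, diagnostic_allele=allele,
                informativeness="full" if full else "partial",
                weight=1.0 if full else partial_weight))
    return out


# ---------------------------------------------------------------------------
# Viterbi core

def viterbi_path(log_emit: np.ndarray, log_stay: float,
                 log_switch: float) -> np.ndarray:
    """Most likely state path for a uniform-prior, symmetric-switch HMM.

    ``log_emit`` is (n_markers, n_states).  Ties break toward the smaller
    state index (deterministic).
    """
    m, k = log_emit.shape
    score = log_emit[0].astype(float).copy()
    back = np.zeros((m, k), dtype=np.int64)
    for t in range(1, m):
        # from-state score for each to-state: stay vs best switch
        trans = np.full((k, k), log_switch)
        np.fill_diagonal(trans, log_stay)
        cand = score[:, None] + trans  # [from, to]
        back[t] = np.argmax(cand, axis=0)
        score = cand[back[t], np.arange(k)] + log_emit[t]
    path = np.empty(m, dtype=np.int64)
    path[-1] = int(np.argmax(score))
    for t in range(m - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _compress_path(path: np.ndarray, positions: np.ndarray,
                   state_names: Sequence[str], log_emit: np.ndarray,
                   strain: str, chrom: str) -> list[MosaicInterval]:
    """Compress a state path to labeled intervals with midpoint boundaries.

    The posterior proxy of a segment is the mean, over its markers, of the
    emission probability of the assigned state normalized across states
    (uninformative markers contribute 1/k).
    """
    m = len(path)
    norm = np.exp(log_emit - log_emit.max(axis=1, keepdims=True))
    norm = norm / norm.sum(axis=1, keepdims=True)
    segments: list[MosaicInterval] = []
    start = 0
    for t in range(1, m + 1):
        if t < m and path[t] == path[start]:
            continue
        start_pos = (int(positions[start]) if start == 0 else
                     (int(positions[start - 1]) + int(positions[start])) // 2 + 1)
        end_pos = (int(positions[t - 1]) if t == m else
                   (int(positions[t - 1]) + int(positions[t])) // 2)
        proxy = float(norm[start:t, int(path[start])].mean())
        segments.append(MosaicInterval(
            strain=strain,
            bounds=GenomicInterval(chrom=chrom, start_pos=start_pos,
                                   end_pos=end_pos, start_idx=start,
                                   end_idx=t - 1),
            label=state_names[int(path[start])],
            mean_posterior_proxy=proxy))
        start = t
    return segments


def subspecies_log_emissions(calls: np.ndarray,
                             diagnostics: Sequence[DiagnosticSNP],
                             marker_indices: Sequence[int],
                             params: HmmParams) -> np.ndarray:
    """(n_diag_markers, 3) log-emission table for one strain.

    ``calls`` are the strain's codes at ``marker_indices`` (the sorted
    unique diagnostic marker indices).
    """
    diag_at: dict[int, list[DiagnosticSNP]] = {}
    for d in diagnostics:
        diag_at.setdefault(d.marker_index, []).append(d)
    log_hit = np.log1p(-params.epsilon)
    log_miss = np.log(params.epsilon / 2.0)
    emit = np.zeros((len(marker_indices), len(SUBSPECIES)))
    state_of = {s: i for i, s in enumerate(SUBSPECIES)}
    for t, j in enumerate(marker_indices):
        c = int(calls[t])
        if c in (HET, MISSING):
            continue
        for d in diag_at.get(j, ()):
            if c != d.diagnostic_allele:
                continue
            s = state_of[d.subspecies]
            for k in range(len(SUBSPECIES)):
                emit[t, k] += d.weight * (log_hit if k == s else log_miss)
    return emit


def subspecies_viterbi(matrix: GenotypeMatrix, strain: str,
                       diagnostics: Sequence[DiagnosticSNP],
                       params: HmmParams = HmmParams()) -> list[MosaicInterval]:
    """Subspecific-origin mosaic of one strain over its diagnostic markers."""
    if not diagnostics:
        raise ValueError("no diagnostic SNPs supplied")
    i = matrix.strain_index(strain)
    marker_indices = sorted({d.marker_index for d in diagnostics})
    calls = matrix.calls[i, marker_indices]
    emit = subspecies_log_emissions(calls, diagnostics, marker_indices, params)
    if not np.any(emit != 0.0):
        raise ValueError(
            f"strain {strain!r} has no informative diagnostic calls")
    k = len(SUBSPECIES)
    path = viterbi_path(emit, np.log1p(-(k - 1) * params.rho),
                        np.log(params.rho))
    positions = matrix.positions()[marker_indices]
    chrom = matrix.markers[marker_indices[0]].chrom
    return _compress_path(path, positions, SUBSPECIES, emit, strain, chrom)


def het_log_emissions(calls: np.ndarray, params: HmmParams) -> np.ndarray:
    """(n_markers, 2) log-emissions for the inbred/heterozygous HMM.

    ``calls`` use genotype codes: 0/1 are homozygous observations, 2 is a
    heterozygous call, -1 missing (emits 1 in both states).
    """
    emit = np.zeros((len(calls), 2))
    is_het = calls == HET
    is_hom = (calls == 0) | (calls == 1)
    emit[is_het, 0] = np.log(params.het_err)
    emit[is_het, 1] = np.log(params.het_emit)
    emit[is_hom, 0] = np.log1p(-params.het_err)
    emit[is_hom, 1] = np.log1p(-params.het_emit)
    return emit


def heterozygosity_viterbi(matrix: GenotypeMatrix, strain: str,
                           params: HmmParams = HmmParams()) -> list[MosaicInterval]:
    """Inbred/heterozygous block mosaic of one strain over all markers."""
    i = matrix.strain_index(strain)
    calls = matrix.calls[i]
    if not np.any(calls != MISSING):
        raise ValueError(f"strain {strain!r} has no non-missing calls")
    emit = het_log_emissions(calls, params)
    path = viterbi_path(emit, np.log1p(-params.rho), np.log(params.rho))
    from .genotype_model import require_single_chromosome
    chrom = require_single_chromosome(matrix)
    return _compress_path(path, matrix.positions(), HET_STATES, emit,
                          strain, chrom)


def write_diagnostics_table(diagnostics: Sequence[DiagnosticSNP],
                            matrix: GenotypeMatrix, path: str) -> None:
    """Tab-separated diagnostic SNP export (marker, pos, subspecies, allele,
    informativeness, weight); externally derived weights can be re-imported
    with :func:`read_diagnostics_table`."""
    with open(path, "w") as fh:
        fh.write("marker\tpos\tsubspecies\tallele\tinformativeness\tweight\n")
        for d in diagnostics:
            m = matrix.markers[d.marker_index]
            major, minor = matrix.allele_labels[d.marker_index]
            letter = major if d.diagnostic_allele == 0 else minor
            fh.write(f"{d.marker_index}\t{m.pos}\t{d.subspecies}\t{letter}"
                     f"\t{d.informativeness}\t{d.weight:g}\n")


def read_diagnostics_table(path: str,
                           matrix: GenotypeMatrix) -> list[DiagnosticSNP]:
    out: list[DiagnosticSNP] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker\t"):
            raise ValueError(f"not a diagnostics table: {path}")
        for ln in fh:
            marker, _pos, sub, letter, info, weight = ln.rstrip("\n").split("\t")
            j = int(marker)
            major, minor = matrix.allele_labels[j]
            allele = 0 if letter == major else 1
            out.append(DiagnosticSNP(
                marker_index=j, subspecies=sub, diagnostic_allele=allele,
                informativeness=info, weight=float(weight)))
    return out
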