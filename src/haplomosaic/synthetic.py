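"""Ground-truthed synthetic strain panels.

Emulates the structure of a laboratory mouse panel: a set of founder
haplotypes drawn from three subspecies, inbred strains that are mosaics of
those founders, genotyping error, missing data, and residual
heterozygosity in "wild" samples.  Every downstream module can be
exercised against the recorded truth without any external data.

The model is deliberately simple: founder alleles are independent across
markers (no within-founder LD beyond the mosaic structure itself), a
fixed fraction of markers per subspecies carry a private variant shared by
all of that subspecies' founders (guaranteeing fully-informative
diagnostic SNPs), and strain mosaics switch founders at a
Poisson-distributed number of uniformly placed breakpoints.  The first
``n_founders`` strains are emitted as pure copies of the founders and play
the role of the wild-derived reference panel of known subspecies.

Generation order per strain: founder alleles -> heterozygosity injection
(designated wild strains only) -> allele-flip errors -> missing data.
Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_model import GenotypeMatrix, matrix_from_letters
from .mosaic_hmm import SUBSPECIES

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Synthetic panel parameters.

    switch_rate is the expected number of founder breakpoints per mosaic
    strain; het_region_fraction the fraction of the chromosome made
    heterozygous in each designated wild strain; private_rate the fraction
    of markers carrying a subspecies-private variant, per subspecies.
    """

    n_founders: int = 8
    founders_per_subspecies: tuple[tuple[str, int], ...] = (
        ("domesticus", 4), ("musculus", 2), ("castaneus", 2))
    n_strains: int = 50
    n_markers: int = 500
    chrom_length_bp: int = 2_000_000
    switch_rate: float = 3.0
    miss_rate: float = 0.02
    err_rate: float = 0.01
    het_region_fraction: float = 0.0
    het_call_rate: float = 0.5
    private_rate: float = 0.10
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "err_rate", "het_region_fraction",
                     "het_call_rate", "private_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.switch_rate < 0:
            raise ValueError("switch_rate must be >= 0")
        for name in ("n_founders", "n_strains", "n_markers", "chrom_length_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        subs = [s for s, _ in self.founders_per_subspecies]
        if sorted(subs) != sorted(set(subs)) or not set(subs) <= set(SUBSPECIES):
            raise ValueError(f"founders_per_subspecies keys must be unique "
                             f"subspecies from {SUBSPECIES}")
        if sum(k for _, k in self.founders_per_subspecies) != self.n_founders:
            raise ValueError("founders_per_subspecies must sum to n_founders")
        if any(k < 1 for _, k in self.founders_per_subspecies):
            raise ValueError("each subspecies needs >= 1 founder")
        if self.n_strains < self.n_founders:
            raise ValueError("n_strains must be >= n_founders (the pure "
                             "reference strains)")
        if self.n_markers > self.chrom_length_bp:
            raise ValueError("more markers than base pairs")


@dataclass
class SimTruth:
    """Recorded ground truth of one simulated panel.

    ``founder_segments[strain]`` is a list of (start_bp, end_bp, founder_id)
    tiling [1, chrom_length_bp]; subspecies segments follow from founder
    subspecies.  ``het_regions[strain]`` lists injected (start_bp, end_bp)
    heterozygous regions.  ``founder_alleles`` is the pre-error
    (n_founders, n_markers) 0/1 allele table and is consistent with the
    emitted genotypes before heterozygosity/error/missing injection.
    """

    params: SimParams
    positions: np.ndarray
    founder_subspecies: list[str]
    founder_alleles: np.ndarray
    founder_segments: dict[str, list[tuple[int, int, int]]]
    het_regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def subspecies_segments(self, strain: str) -> list[tuple[int, int, str]]:
        """Founder segments collapsed to subspecies labels."""
        out: list[tuple[int, int, str]] = []
        for start, end, fid in self.founder_segments[strain]:
            sub = self.founder_subspecies[fid]
            if out and out[-1][2] == sub and out[-1][1] + 1 == start:
                out[-1] = (out[-1][0], end, sub)
            else:
                out.append((start, end, sub))
        return out

    def founder_at(self, strain: str, pos: int) -> int:
        for start, end, fid in self.founder_segments[strain]:
            if start <= pos <= end:
                return fid
        raise ValueError(f"position {pos} outside simulated chromosome")

    def subspecies_at(self, strain: str, pos: int) -> str:
        return self.founder_subspecies[self.founder_at(strain, pos)]

    def n_breakpoints(self, strain: str) -> int:
        return len(self.founder_segments[strain]) - 1

    def wild_strains(self) -> list[str]:
        return sorted(self.het_regions)


def strain_name(i: int) -> str:
    return f"S{i:03d}"


def simulate_panel(params: SimParams) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a founder-mosaic inbred panel with recorded truth."""
    rng = np.random.default_rng(params.seed)
    m, L = params.n_markers, params.chrom_length_bp
    positions = np.sort(rng.choice(L, size=m, replace=False)) + 1

    founder_subspecies: list[str] = []
    for sub, k in params.founders_per_subspecies:
        founder_subspecies.extend([sub] * k)

    # founder alleles: independent Bernoulli(1/2), then subspecies-private
    # variants on disjoint marker subsets so diagnostic SNPs always exist
    alleles = rng.integers(0, 2, size=(params.n_founders, m), dtype=np.int8)
    n_private = int(params.private_rate * m)
    reserved = rng.permutation(m)[:n_private * len(params.founders_per_subspecies)]
    for s_i, (sub, _k) in enumerate(params.founders_per_subspecies):
        block = reserved[s_i * n_private:(s_i + 1) * n_private]
        for fid, fsub in enumerate(founder_subspecies):
            alleles[fid, block] = 1 if fsub == sub else 0

    # per-marker nucleotide labels for the two simulated alleles
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref, alt = _BASES[ref_idx], _BASES[alt_idx]

    strains = [strain_name(i) for i in range(params.n_strains)]
    segments: dict[str, list[tuple[int, int, int]]] = {}
    letters = np.empty((params.n_strains, m), dtype="U1")
    for i, name in enumerate(strains):
        if i < params.n_founders:
            segs = [(1, L, i)]  # pure reference copy of founder i
        else:
            n_bp = int(rng.poisson(params.switch_rate))
            cuts = np.sort(rng.integers(2, L + 1, size=n_bp))
            cuts = np.unique(cuts)
            founders = [int(rng.integers(0, params.n_founders))]
            for _ in cuts:
                # always switch to a *different* founder so every drawn
                # breakpoint is a real one
                nxt = int(rng.integers(0, params.n_founders - 1))
                if nxt >= founders[-1]:
                    nxt += 1
                founders.append(nxt)
            bounds = [1, *cuts.tolist(), L + 1]
            segs = [(bounds[t], bounds[t + 1] - 1, founders[t])
                    for t in range(len(founders))]
        segments[name] = segs
        row = np.empty(m, dtype=np.int8)
        for start, end, fid in segs:
            sel = (positions >= start) & (positions <= end)
            row[sel] = alleles[fid, sel]
        letters[i] = np.where(row == 0, ref, alt)

    truth = SimTruth(params=params, positions=positions,
                     founder_subspecies=founder_subspecies,
                     founder_alleles=alleles, founder_segments=segments)

    # residual heterozygosity in designated wild strains (never references)
    if params.het_region_fraction > 0.0:
        n_wild = max(1, round(0.1 * params.n_strains))
        n_wild = min(n_wild, params.n_strains - params.n_founders)
        region_len = max(1, int(params.het_region_fraction * L))
        for i in range(params.n_strains - n_wild, params.n_strains):
            start = int(rng.integers(1, max(L - region_len + 1, 2)))
            end = start + region_len - 1
            truth.het_regions[strains[i]] = [(start, end)]
            inside = (positions >= start) & (positions <= end)
            flips = rng.random(m) < params.het_call_rate
            letters[i, inside & flips] = "H"

    # genotyping error: homozygous calls flip to the other allele
    err = rng.random(letters.shape) < params.err_rate
    hom = (letters != "H") & (letters != "N")
    flip = err & hom
    letters[flip] = np.where(letters[flip] == ref[np.nonzero(flip)[1]],
                             alt[np.nonzero(flip)[1]],
                             ref[np.nonzero(flip)[1]])

    # missing data on any call
    miss = rng.random(letters.shape) < params.miss_rate
    letters[miss] = "N"

    chroms = [params.chrom] * m
    matrix = matrix_from_letters(strains, chroms, positions.tolist(), letters)
    return matrix, truth


def labeled_reference_subset(truth: SimTruth,
                             k_per_subspecies: int) -> dict[str, str]:
    """Labels for k pure (single-segment) strains per subspecies.

    Selection is deterministic: lowest strain indices first.  Raises when a
    subspecies has fewer than k pure strains.
    """
    if k_per_subspecies < 1:
        raise ValueError("k_per_subspecies must be >= 1")
    present = {s for s, _ in truth.params.founders_per_subspecies}
    labels: dict[str, str] = {}
    for sub in (s for s in SUBSPECIES if s in present):
        pure = [name for name in sorted(truth.founder_segments)
                if len(truth.founder_segments[name]) == 1
                and truth.founder_subspecies[
                    truth.founder_segments[name][0][2]] == sub]
        if len(pure) < k_per_subspecies:
            raise ValueError(
                f"only {len(pure)} pure strains for {sub}, "
                f"need {k_per_subspecies}")
        for name in pure[:k_per_subspecies]:
            labels[name] = sub
    return labels


def full_reference_labels(truth: SimTruth) -> dict[str, str]:
    """Label every pure (single-segment) strain with its founder's subspecies.

    Using the complete reference panel avoids spurious diagnostic calls
    that arise when some founders are left unlabeled.
    """
    labels: dict[str, str] = {}
    for name, segs in sorted(truth.founder_segments.items()):
        if len(segs) == 1:
            labels[name] = truth.founder_subspecies[segs[0][2]]
    return labels


def write_truth_beds(truth: SimTruth, prefix: str) -> None:
    """Truth tables as BED: founder segments, subspecies segments, het regions."""
    chrom = truth.params.chrom
    with open(f"{prefix}founder_segments.bed", "w") as fh:
        for name in sorted(truth.founder_segments):
            for start, end, fid in truth.founder_segments[name]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}:F{fid}\n")
    with open(f"{prefix}subspecies_segments.bed", "w") as fh:
        for name in sorted(truth.founder_segments):
            for start, end, sub in truth.subspecies_segments(name):
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}:{sub}\n")
    with open(f"{prefix}het_regions.bed", "w") as fh:
        for name in sorted(truth.het_regions):
            for start, end in truth.het_regions[name]:
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")


def write_labels_table(labels: dict[str, str], path: str) -> None:
    """Strain metadata table for the labeled reference subset."""
    with open(path, "w") as fh:
        for name in sorted(labels):
            fh.write(f"{name}\twild_derived\t{labels[name]}\n")
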