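"""Summary statistics over genotype samples.

Nucleotide diversity (pi), Watterson's theta and segregating sites are
computed from allele/mutation frequencies, so they cost O(total mutations)
rather than O(n^2) pairwise comparisons; ``pi`` nevertheless equals the
average pairwise difference count exactly.  ``pi`` is reported per pair of
genotypes (difference counts); in sequence mode a per-site normalisation is
reported alongside, never silently substituted.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .model import (BASES, ConfigurationError, PopulationState, decode_sequence,
                    encode_sequence)

__all__ = [
    "DiversitySummary",
    "JC69SaturationError",
    "pairwise_pi",
    "segregating_sites",
    "watterson_theta",
    "diversity_summary",
    "state_diversity",
    "jc69_distance",
    "write_fasta",
    "read_fasta",
]


class JC69SaturationError(ValueError):
    """Raised when raw divergence p >= 3/4, outside the JC69 domain."""


@dataclass(frozen=True)
class DiversitySummary:
    """pi, Watterson's theta and segregating sites for one genotype sample."""

    pi: float
    watterson_theta: float
    segregating_sites: int
    sample_size: int
    pi_per_site: Optional[float] = None  # sequence mode only


def _is_set_sample(sample) -> bool:
    return len(sample) > 0 and isinstance(sample[0], (set, frozenset))


def _as_matrix(sample) -> np.ndarray:
    """Normalise a sequence-mode sample to an (n, L) uint8 matrix."""
    rows = [encode_sequence(g) if isinstance(g, str) else np.asarray(g, dtype=np.uint8)
            for g in sample]
    lengths = {r.shape[0] for r in rows}
    if len(lengths) != 1:
        raise ConfigurationError("all sequences in a sample must have equal length")
    return np.vstack(rows)


def _mutation_counts(sample) -> Counter:
    counts: Counter = Counter()
    for g in sample:
        counts.update(g)
    return counts


def _site_pair_stats(sample) -> Tuple[float, int, int, Optional[int]]:
    """(sum over sites of differing pair count, S, n, L or None)."""
    sample = list(sample)
    n = len(sample)
    if n < 2:
        raise ConfigurationError("diversity statistics require a sample of size >= 2")
    if _is_set_sample(sample):
        counts = _mutation_counts(sample)
        diff_pairs = sum(x * (n - x) for x in counts.values())
        s = sum(1 for x in counts.values() if 0 < x < n)
        return float(diff_pairs), s, n, None
    mat = _as_matrix(sample)
    allele = np.stack([(mat == b).sum(axis=0) for b in range(4)])  # (4, L)
    same = (allele * (allele - 1) // 2).sum(axis=0)
    total = n * (n - 1) // 2
    diff_pairs = float((total - same).sum())
    s = int(((allele > 0).sum(axis=0) > 1).sum())
    return diff_pairs, s, n, mat.shape[1]


def pairwise_pi(sample) -> float:
    """Mean pairwise difference count over all unordered genotype pairs.

    Accepts mutation-id sets (infinite-sites mode) or equal-length sequences
    (ACGT strings or 0..3 arrays). Reported per pair, not per site.
    """
    diff_pairs, _, n, _ = _site_pair_stats(sample)
    return diff_pairs / (n * (n - 1) / 2)


def segregating_sites(sample) -> int:
    """Number of mutations/sites present in >= 1 but not all sampled genotypes."""
    _, s, _, _ = _site_pair_stats(sample)
    return s


def harmonic_number(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def watterson_theta(sample) -> float:
    """Watterson's estimator: S divided by the harmonic number a_{n-1}."""
    _, s, n, _ = _site_pair_stats(sample)
    return s / harmonic_number(n - 1)


def diversity_summary(sample) -> DiversitySummary:
    diff_pairs, s, n, length = _site_pair_stats(sample)
    pi = diff_pairs / (n * (n - 1) / 2)
    return DiversitySummary(
        pi=pi,
        watterson_theta=s / harmonic_number(n - 1),
        segregating_sites=s,
        sample_size=n,
        pi_per_site=(pi / length) if length else None)


def _pool_ids(state: PopulationState, pool: str) -> np.ndarray:
    if pool == "active":
        return state.active
    if pool == "dormant":
        return state.dormant
    if pool == "all":
        return np.concatenate([state.active, state.dormant])
    raise ConfigurationError(f"unknown pool {pool!r}; expected active, dormant or all")


def state_diversity(state: PopulationState, pool: str = "active") -> DiversitySummary:
    """Diversity summary straight from a population state.

    Defaults to the full active pool; ``pool='all'`` samples active and
    dormant individuals jointly. For the infinite-sites encoding this walks
    the haplotype forest instead of materialising mutation sets.
    """
    if state.mode == "biallelic":
        raise ConfigurationError("diversity statistics are defined for mutation-carrying modes")
    ids = _pool_ids(state, pool)
    n = ids.shape[0]
    if n < 2:
        raise ConfigurationError("diversity statistics require a sample of size >= 2")
    if state.mode == "sequence":
        return diversity_summary(list(ids))
    uniq, cnt = np.unique(ids, return_counts=True)
    mut_counts: Counter = Counter()
    parent = state.store.parent
    for hid, k in zip(uniq, cnt):
        h = int(hid)
        while h > 0:
            mut_counts[h] += int(k)
            h = int(parent[h])
    diff_pairs = sum(x * (n - x) for x in mut_counts.values())
    s = sum(1 for x in mut_counts.values() if 0 < x < n)
    pairs = n * (n - 1) / 2
    return DiversitySummary(
        pi=diff_pairs / pairs,
        watterson_theta=s / harmonic_number(n - 1),
        segregating_sites=s,
        sample_size=n)


def jc69_distance(seq_a, seq_b, on_saturation: str = "raise") -> float:
    """Jukes--Cantor corrected distance between two equal-length sequences.

    With p the proportion of differing sites, returns -(3/4) ln(1 - 4p/3),
    the expected number of substitutions per site under the one-parameter
    model. ``p >= 3/4`` lies outside the model's domain (saturation): raised
    as :class:`JC69SaturationError` by default, or returned as ``inf`` with
    ``on_saturation='inf'``; never a silent finite number.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a, dtype=np.uint8)
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b, dtype=np.uint8)
    if a.shape != b.shape:
        raise ConfigurationError("JC69 distance requires equal-length sequences")
    p = float(np.mean(a != b))
    if p >= 0.75:
        if on_saturation == "inf":
            return math.inf
        raise JC69SaturationError(
            f"raw divergence p={p:.4f} >= 3/4: JC69 distance undefined (saturated)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def write_fasta(state: PopulationState, path) -> None:
    """Export a sequence-mode population as FASTA (active_<i> / dormant_<j>)."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if state.mode != "sequence":
        raise ConfigurationError("FASTA export is defined for sequence mode")
    records = [SeqRecord(Seq(decode_sequence(row)), id=f"active_{i}", description="")
               for i, row in enumerate(state.active)]
    records += [SeqRecord(Seq(decode_sequence(row)), id=f"dormant_{j}", description="")
                for j, row in enumerate(state.dormant)]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file into (identifier, sequence string) pairs."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
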