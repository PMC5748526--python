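"""Per-generation inner loops of the Moran engine.

Each kernel consumes *pre-drawn* arrays of random variates, so the numba-jitted
and pure-Python implementations consume the random stream identically and
produce bit-identical states.  The jitted path is used when numba imports
cleanly; the Python path is the reference implementation and is exercised
directly by the test suite for agreement.

All kernels perform exactly ``N`` sequential birth--death events: event ``e``
copies the genotype of ``parents[e]``, possibly mutates the copy, and writes it
over ``victims[e]``.  The sequential order matters: an offspring created by
event ``e`` may be the parent of event ``e+1``.
"""

from __future__ import annotations

import numpy as np


def _py_biallelic_generation(active, s, u_parent, victims):
    """One generation of biallelic Moran events with selection.

    ``active`` is a uint8 0/1 array (1 = beneficial, relative fitness 1+s).
    Parent choice is fitness-weighted by allele class only, which is
    distribution-identical to weighting individuals because carriers are
    exchangeable. Returns the updated beneficial count.
    """
    n = active.shape[0]
    k = 0
    for i in range(n):
        k += int(active[i])
    for e in range(n):
        kf = k * (1.0 + s)
        p_ben = kf / (kf + (n - k))
        parent_ben = 1 if u_parent[e] < p_ben else 0
        v = victims[e]
        k += parent_ben - int(active[v])
        active[v] = parent_ben
    return k


def _py_infinite_sites_generation(geno, parents, victims, mut_flags, next_id,
                                  hap_parent, hap_depth):
    """One neutral generation under the infinite-sites model.

    Genotypes are haplotype ids into the (hap_parent, hap_depth) forest; a
    mutation creates a fresh haplotype whose id doubles as the globally unique
    mutation identifier. Returns the updated next_id.
    """
    n = geno.shape[0]
    for e in range(n):
        g = geno[parents[e]]
        if mut_flags[e]:
            hap_parent[next_id] = g
            hap_depth[next_id] = hap_depth[g] + 1
            g = next_id
            next_id += 1
        geno[victims[e]] = g
    return next_id


def _py_sequence_generation(seqs, parents, victims, mut_ptr, mut_sites,
                            mut_offsets):
    """One neutral generation in explicit-sequence mode.

    ``seqs`` is an (N, L) uint8 matrix over the alphabet {0,1,2,3}. Mutations
    for event ``e`` are the CSR slice mut_ptr[e]:mut_ptr[e+1] of (site, offset)
    pairs; a substitution moves a base to one of the three other bases,
    ``(base + 1 + offset) % 4`` with offset in {0,1,2}.
    """
    n = seqs.shape[0]
    length = seqs.shape[1]
    for e in range(n):
        p = parents[e]
        v = victims[e]
        if p != v:
            for j in range(length):
                seqs[v, j] = seqs[p, j]
        for m in range(mut_ptr[e], mut_ptr[e + 1]):
            site = mut_sites[m]
            seqs[v, site] = (seqs[v, site] + 1 + mut_offsets[m]) % 4


try:  # pragma: no cover - exercised implicitly on numba installs
    from numba import njit

    biallelic_generation = njit(cache=False, nogil=True)(_py_biallelic_generation)
    infinite_sites_generation = njit(cache=False, nogil=True)(
        _py_infinite_sites_generation)
    sequence_generation = njit(cache=False, nogil=True)(_py_sequence_generation)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    biallelic_generation = _py_biallelic_generation
    infinite_sites_generation = _py_infinite_sites_generation
    sequence_generation = _py_sequence_generation
    HAVE_NUMBA = False
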