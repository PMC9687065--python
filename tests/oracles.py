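"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain nucleotide/element enumeration, sharing
no helper code with the package.
"""

from __future__ import annotations

from math import comb

_STOPS = ("TAA", "TAG", "TGA")


def brute_dej(exon_lens_5to3, cds_end, threshold):
    """(has_dej, distance) by walking the transcript exon by exon."""
    if len(exon_lens_5to3) < 2:
        return False, None
    position = 0
    junctions = []
    for length in exon_lens_5to3[:-1]:
        position = position + length
        junctions.append(position)
    distance = junctions[-1] - cds_end
    return distance > threshold, float(distance)


def brute_uorfs(sequence, cds_start, min_codons):
    """Count qualifying upstream ORFs by scanning every nucleotide."""
    sequence = sequence.upper()
    count = 0
    for start in range(cds_start):
        if sequence[start : start + 3] != "ATG":
            continue
        stop_end = None
        j = start + 3
        while j + 3 <= len(sequence):
            if sequence[j : j + 3] in _STOPS:
                stop_end = j + 3
                break
            j += 3
        if stop_end is None:
            continue
        if stop_end > cds_start:
            continue
        if (stop_end - start) // 3 < min_codons:
            continue
        count += 1
    return count


def brute_utr3(transcript_length, cds_end):
    return transcript_length - cds_end


def brute_longest_orf(sequence):
    """(start, end) of the longest ATG..stop ORF, or None."""
    sequence = sequence.upper()
    best = None
    for start in range(len(sequence) - 2):
        if sequence[start : start + 3] != "ATG":
            continue
        j = start + 3
        while j + 3 <= len(sequence):
            if sequence[j : j + 3] in _STOPS:
                if best is None or j + 3 - start > best[1] - best[0]:
                    best = (start, j + 3)
                break
            j += 3
    return best


def brute_ks(a, b):
    """sup |F_a - F_b| evaluated at every pooled point."""
    d = 0.0
    for x in sorted(set(list(a) + list(b))):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def brute_fisher(a, b, c, d):
    """Two-sided Fisher exact p by hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p_k = prob(k)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(total, 1.0)


def brute_bh(pvalues):
    """Benjamini-Hochberg adjusted p-values by direct definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
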