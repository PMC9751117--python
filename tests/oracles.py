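"""Independent brute-force oracles shared by the unit and acceptance suites."""

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str) -> int:
    """Maximum base pairs over all nested structures with hairpin loops >= 3.

    Recursive enumeration over every admissible pair set; exponential, only
    usable for short sequences (<= ~14 nt).
    """

    def best(i: int, j: int) -> int:
        if j - i <= 3:
            return 0
        result = best(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                result = max(result, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return result

    return best(0, len(seq) - 1)


def naive_kmer_counts(seq: str, k: int) -> dict:
    """Sliding-window k-mer counting, one window at a time."""
    out: dict = {}
    for i in range(len(seq) - k + 1):
        out[seq[i : i + k]] = out.get(seq[i : i + k], 0) + 1
    return out
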