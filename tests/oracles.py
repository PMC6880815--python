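"""Independent brute-force oracles used to verify the implementation.

Each oracle is deliberately written as the most transparent possible
computation (full DP tables, exhaustive window / assignment / formula
enumeration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices


def sw_score_oracle(a: str, b: str, matrix_name: str, gap_open: int, gap_extend: int) -> float:
    """Full Gotoh dynamic-programming table; gap of length k costs open + k*extend."""
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            s = mat[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def window_chains_oracle(scaffold_genes, hit_gene_ids, max_gap_bp, max_intervening):
    """All maximal valid windows of hit-bearing genes on one scaffold.

    Enumerates every contiguous window [i..j] over the ordered hit-bearing
    genes, checks the dual adjacency rule for every consecutive pair inside
    it, and keeps windows that cannot be extended on either side.
    Returns tuples of gene ids.
    """
    marked = [
        (pos, g) for pos, g in enumerate(scaffold_genes) if g.id in hit_gene_ids
    ]
    k = len(marked)

    def link_ok(u, v):
        (pu, gu), (pv, gv) = marked[u], marked[v]
        return (gv.start - gu.end) <= max_gap_bp and (pv - pu - 1) <= max_intervening

    def window_valid(i, j):
        return all(link_ok(t, t + 1) for t in range(i, j))

    out = []
    for i in range(k):
        for j in range(i, k):
            if not window_valid(i, j):
                continue
            if i > 0 and link_ok(i - 1, i):
                continue  # extensible left
            if j < k - 1 and link_ok(j, j + 1):
                continue  # extensible right
            out.append(tuple(marked[t][1].id for t in range(i, j + 1)))
    return out


def optimal_assignment_oracle(identity_matrix, min_identity):
    """Best one-to-one gene pairing by exhaustive enumeration.

    identity_matrix: dict (gene_a, gene_b) -> identity.  Enumerates every
    injective mapping over subsets of A-genes and returns the pair set of
    maximal total identity among pairs >= min_identity (ties resolved by
    larger pair count, then lexicographic pair set, for determinism).
    """
    genes_a = sorted({a for a, _ in identity_matrix})
    genes_b = sorted({b for _, b in identity_matrix})
    eligible = {
        (a, b): v for (a, b), v in identity_matrix.items() if v >= min_identity
    }
    best_pairs, best_key = frozenset(), (-1.0, 0, ())
    for r in range(0, min(len(genes_a), len(genes_b)) + 1):
        for subset_a in itertools.combinations(genes_a, r):
            for perm_b in itertools.permutations(genes_b, r):
                pairs = tuple(zip(subset_a, perm_b))
                if any(p not in eligible for p in pairs):
                    continue
                total = sum(eligible[p] for p in pairs)
                key = (total, len(pairs), tuple(sorted(pairs)))
                if key > best_key:
                    best_key, best_pairs = key, frozenset(pairs)
    return best_pairs


def motif_scan_oracle(seq: str, pattern_positions) -> list[int]:
    """Position-by-position pattern check (pattern: list of sets or None)."""
    L, k = len(seq), len(pattern_positions)
    out = []
    for start in range(L - k + 1):
        ok = True
        for off, allowed in enumerate(pattern_positions):
            if allowed is not None and seq[start + off] not in allowed:
                ok = False
                break
        if ok:
            out.append(start)
    return out


# scalar CHO formula enumeration, independent of the vectorised search
_MASS = {"C": 12.0, "H": 1.00782503207, "O": 15.9949146196, "Na": 22.9897692809}
_ELECTRON = 0.000548579909


def cho_formula_oracle(observed_mz, adduct_delta, tolerance_ppm, c_max, h_max, o_max):
    """Nested-loop enumeration of neutral CxHyOz matching an adduct ion m/z.

    adduct_delta: element->count applied to the neutral formula (charge +1
    assumed).  Returns [(c, h, o, ppm)] sorted by |ppm|.
    """
    out = []
    for c in range(c_max + 1):
        for h in range(h_max + 1):
            for o in range(o_max + 1):
                if c + h + o == 0:
                    continue
                counts = {"C": c, "H": h, "O": o}
                for el, d in adduct_delta.items():
                    counts[el] = counts.get(el, 0) + d
                if any(v < 0 for v in counts.values()):
                    continue
                mz = sum(_MASS[el] * n for el, n in counts.items()) - _ELECTRON
                ppm = (observed_mz - mz) / mz * 1e6
                if abs(ppm) > tolerance_ppm:
                    continue
                dbe = c - h / 2 + 1  # neutral CHO
                if not (0 <= dbe <= 20) or dbe != int(dbe):
                    continue
                out.append((c, h, o, ppm))
    out.sort(key=lambda t: abs(t[3]))
    return out
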