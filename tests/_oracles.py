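"""Independent brute-force oracles used to cross-check the package.

Everything here re-derives results from the rule text by exhaustive window
enumeration (locus calling) or closed forms (least squares), sharing no
code path with the implementation under test.
"""

from __future__ import annotations

ABSORB = {"SUSC", "SUSD", "CAZYME", "SULFATASE", "REGULATOR"}


def _split_by_contig(genes):
    out = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start)):
        out.setdefault(g.contig, []).append(g)
    return out


def _is_maximal_pair_window(cgenes, roles, i, j):
    """Window [i..j] is a maximal SusC-run->SusD-run block (transcription order)."""
    strand = cgenes[i].strand
    if any(cgenes[m].strand != strand for m in range(i, j + 1)):
        return False
    first, second = ("SUSC", "SUSD") if strand == "+" else ("SUSD", "SUSC")
    ok = False
    for k in range(i, j):
        if all(roles[m] == first for m in range(i, k + 1)) and \
           all(roles[m] == second for m in range(k + 1, j + 1)):
            ok = True
            break
    if not ok:
        return False
    # maximality: cannot extend the leading or trailing run
    if i > 0 and cgenes[i - 1].strand == strand and roles[i - 1] == first:
        return False
    if j + 1 < len(cgenes) and cgenes[j + 1].strand == strand and roles[j + 1] == second:
        return False
    return True


def oracle_pair_windows(cgenes, roles):
    """All maximal pair windows [i, j] on one contig."""
    n = len(cgenes)
    found = []
    for i in range(n):
        for j in range(i + 1, n):
            if _is_maximal_pair_window(cgenes, roles, i, j):
                found.append((i, j))
    return found


def _side_valid(cgenes, roles, lo, hi, max_gap_genes, max_gap_bp):
    """Genes lo..hi can be appended to a block whose edge is at hi+1 (left side)
    or lo-1 (right side): bounded unknown runs and intergenic distances."""
    run = 0
    for m in range(lo, hi + 1):
        if roles[m] == "UNKNOWN":
            run += 1
            if run > max_gap_genes:
                return False
        else:
            run = 0
    for m in range(lo, hi + 1):
        nxt = m + 1
        if nxt <= hi + 1:
            if cgenes[nxt].start - cgenes[m].end - 1 > max_gap_bp:
                return False
    return True


def oracle_predict(genes, role_names, max_gap_genes=2, max_gap_bp=5000):
    """PUL set by exhaustive enumeration: maximal pair windows, declaratively
    maximal extensions, overlap merging.  Returns a set of
    (contig, span_start, span_end, frozenset(member gene_ids), n_pair_blocks).
    """
    role_of = {g.gene_id: r for g, r in zip(
        sorted(genes, key=lambda g: (g.contig, g.start)), role_names
    )}
    results = []
    for contig, cgenes in _split_by_contig(genes).items():
        roles = [role_of[g.gene_id] for g in cgenes]
        windows = []
        for (i, j) in oracle_pair_windows(cgenes, roles):
            best_l = i
            for L in range(i - 1, -1, -1):
                if roles[L] in ABSORB and _side_valid(
                    cgenes, roles, L, i - 1, max_gap_genes, max_gap_bp
                ):
                    best_l = L
            best_r = j
            for R in range(j + 1, len(cgenes)):
                # mirror: genes j+1..R appended to the right edge
                if roles[R] in ABSORB and _right_valid(
                    cgenes, roles, j + 1, R, max_gap_genes, max_gap_bp
                ):
                    best_r = R
            windows.append((best_l, best_r))
        # merge index ranges that share genes, to a fixpoint
        windows.sort()
        merged = []
        for lo, hi in windows:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        n_blocks = {}
        for (i, j) in oracle_pair_windows(cgenes, roles):
            for wi, (lo, hi) in enumerate(merged):
                if lo <= i and j <= hi:
                    n_blocks[wi] = n_blocks.get(wi, 0) + 1
        for wi, (lo, hi) in enumerate(merged):
            members = cgenes[lo:hi + 1]
            results.append((
                contig,
                min(g.start for g in members),
                max(g.end for g in members),
                frozenset(g.gene_id for g in members),
                n_blocks.get(wi, 0),
            ))
    return set(results)


def _right_valid(cgenes, roles, lo, hi, max_gap_genes, max_gap_bp):
    run = 0
    for m in range(lo, hi + 1):
        if roles[m] == "UNKNOWN":
            run += 1
            if run > max_gap_genes:
                return False
        else:
            run = 0
    for m in range(lo, hi + 1):
        if cgenes[m].start - cgenes[m - 1].end - 1 > max_gap_bp:
            return False
    return True


def puls_as_set(puls):
    """Normalize predict_puls output for comparison with oracle_predict."""
    return {
        (p.contig, p.start, p.end, frozenset(p.member_gene_ids), len(p.pair_blocks))
        for p in puls
    }


# ---------------------------------------------------------------------------
# least squares closed form (normal equations)


def ols_closed_form(x, y):
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept
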