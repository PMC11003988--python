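"""Independent brute-force oracles used to validate the engine.

These stay deliberately naive — literal double loops over the ranked gene
list — so they cannot share a defect with the vectorised implementation.
"""

import numpy as np


def ssgsea_reference(values, gene_ids, member_genes, alpha):
    """Literal ECDF-summation ssGSEA oracle.

    Sorts genes by expression descending (gene ID ascending on ties),
    assigns rank weights N..1, and accumulates P_hit - P_miss position by
    position.
    """
    order = sorted(range(len(gene_ids)), key=lambda i: (-values[i], gene_ids[i]))
    sorted_genes = [gene_ids[i] for i in order]
    n = len(sorted_genes)
    members = set(member_genes) & set(gene_ids)
    n_in = len(members)
    assert 0 < n_in < n
    denom = 0.0
    for pos, g in enumerate(sorted_genes):
        if g in members:
            denom += float(n - pos) ** alpha
    es = 0.0
    for i in range(1, n + 1):
        p_hit = 0.0
        p_miss = 0
        for pos in range(i):
            g = sorted_genes[pos]
            if g in members:
                p_hit += float(n - pos) ** alpha
            else:
                p_miss += 1
        es += p_hit / denom - p_miss / (n - n_in)
    return es


def least_squares_r2_reference(x, y):
    """R^2 of simple OLS via explicit residual sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
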