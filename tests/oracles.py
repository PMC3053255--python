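"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch with plain Python
loops over codon strings, sharing no code paths with the package's
vectorized implementations.
"""

BASES = "UCAG"
PURINES = {"A", "G"}


def all_codons():
    return [a + b + c for a in BASES for b in BASES for c in BASES]


def neighbors_of(codon):
    """(mutant, 1-based position, 'transition'|'transversion') triples."""
    out = []
    for p in range(3):
        for b in BASES:
            if b == codon[p]:
                continue
            mutant = codon[:p] + b + codon[p + 1:]
            same_class = (codon[p] in PURINES) == (b in PURINES)
            out.append((mutant, p + 1, "transition" if same_class else "transversion"))
    return out


def brute_force_ms(code, scale):
    """code: codon->label dict ('*' = stop); scale: aa->value dict."""
    total, n = 0.0, 0
    for codon in all_codons():
        if code[codon] == "*":
            continue
        for mutant, _pos, _cls in neighbors_of(codon):
            if code[mutant] == "*":
                continue
            d = scale[code[codon]] - scale[code[mutant]]
            total += d * d
            n += 1
    return total / n


def brute_force_tms(code, scale, weights):
    """weights: (class, position) -> weight dict."""
    total, wsum = 0.0, 0.0
    for codon in all_codons():
        if code[codon] == "*":
            continue
        for mutant, pos, cls in neighbors_of(codon):
            if code[mutant] == "*":
                continue
            w = weights[(cls, pos)]
            d = scale[code[codon]] - scale[code[mutant]]
            total += w * d * d
            wsum += w
    return total / wsum


def brute_force_event_count(code):
    n = 0
    for codon in all_codons():
        if code[codon] == "*":
            continue
        for mutant, _pos, _cls in neighbors_of(codon):
            if code[mutant] != "*":
                n += 1
    return n


def brute_force_pattern_scores(code, scale):
    """Direct nested-loop version of the pattern I / pattern II proxies."""
    props = {}
    for codon in all_codons():
        if code[codon] != "*":
            props[codon] = scale[code[codon]]

    def variance(vals):
        m = sum(vals) / len(vals)
        return sum((v - m) ** 2 for v in vals) / len(vals)

    def mean_group_var(varying_pos):
        out = []
        for x in BASES:
            for y in BASES:
                group = []
                for v in BASES:
                    codon = [x, y]
                    codon.insert(varying_pos, v)
                    key = "".join(codon)
                    if key in props:
                        group.append(props[key])
                if len(group) >= 2:
                    out.append(variance(group))
        return sum(out) / len(out)

    pattern1 = mean_group_var(0) - mean_group_var(1)

    within, across = [], []
    pyr = {"U", "C"}
    for b1 in BASES:
        for b3 in BASES:
            for a in BASES:
                for b in BASES:
                    if a == b:
                        continue
                    ka, kb = b1 + a + b3, b1 + b + b3
                    if ka in props and kb in props:
                        d2 = (props[ka] - props[kb]) ** 2
                        if (a in pyr) == (b in pyr):
                            within.append(d2)
                        else:
                            across.append(d2)
    pattern2 = sum(across) / len(across) - sum(within) / len(within)
    return pattern1, pattern2
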