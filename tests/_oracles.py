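"""Independent brute-force oracles shared between unit and acceptance tests.

These deliberately avoid the package's vectorized scanning code paths:
everything is plain character comparison and exhaustive enumeration.
"""

from loxkit.genome_model import revcomp


def naive_present(query, fwd, rev, max_amplicon, max_mismatch, circular=False):
    """Quadratic oracle: enumerate every primer placement on both strands by
    character comparison and test every amplifiable combination."""
    q = query.upper()
    L = len(q)
    ext = q + q if circular else q

    def sites(primer):
        out = []
        k = len(primer)
        rc = revcomp(primer)
        limit = L if circular else L - k + 1
        for p in range(max(0, limit)):
            win = ext[p:p + k]
            if sum(a != b for a, b in zip(win, primer)) <= max_mismatch:
                out.append((p, "+"))
            if sum(a != b for a, b in zip(win, rc)) <= max_mismatch:
                out.append((p, "-"))
        return out

    f_sites, r_sites = sites(fwd), sites(rev)
    combos = [(p, r, len(fwd), len(rev)) for (p, s) in f_sites if s == "+"
              for (r, t) in r_sites if t == "-"]
    combos += [(p, r, len(rev), len(fwd)) for (p, s) in r_sites if s == "+"
               for (r, t) in f_sites if t == "-"]
    for pl, pr, kl, kr in combos:
        if circular:
            dist = (pr + kr - pl) % L or L
        else:
            if pr < pl:
                continue
            dist = pr + kr - pl
        if max(kl, kr) <= dist <= max_amplicon:
            return 1
    return 0
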