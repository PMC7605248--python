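"""Independent brute-force oracles shared by test modules."""
import itertools


def brute_force_isoforms(host_d, host_a, te_d, te_a):
    """Enumerate all site subsequences and keep valid splice chains:
    start at a host donor, alternate donor/acceptor with strictly
    increasing coordinates, terminate at the first host acceptor."""
    sites = (
        [(p, "host", "donor") for p in host_d]
        + [(p, "te", "donor") for p in te_d]
        + [(p, "host", "acceptor") for p in host_a]
        + [(p, "te", "acceptor") for p in te_a]
    )
    sites.sort()
    valid = set()
    for r in range(2, len(sites) + 1, 2):
        for combo in itertools.combinations(sites, r):
            ok = combo[0][1] == "host" and combo[0][2] == "donor"
            ok = ok and all(
                c[2] == ("donor" if i % 2 == 0 else "acceptor")
                for i, c in enumerate(combo)
            )
            ok = ok and all(
                not (c[1] == "host" and c[2] == "acceptor") for c in combo[:-1]
            )
            ok = ok and combo[-1][1] == "host" and combo[-1][2] == "acceptor"
            ok = ok and all(
                combo[i][0] < combo[i + 1][0] for i in range(len(combo) - 1)
            )
            if ok:
                valid.add(combo)
    return valid
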