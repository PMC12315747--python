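"""Shared independent oracles for the statistics tests."""

import itertools

import numpy as np


def brute_force_clusters(table, montage, p_thresh=0.05, min_size=2):
    """Exhaustive connected-component search (independent oracle).

    Enumerates all subsets of significant same-sign electrodes and keeps the
    maximal connected ones.
    """
    sig = {r.electrode: r.contrast_t for r in table.itertuples()
           if r.contrast_p < p_thresh}
    adj = {c: set(montage.neighbors(c)) for c in montage.channel_names}

    def connected(subset):
        subset = list(subset)
        reached = {subset[0]}
        frontier = [subset[0]]
        while frontier:
            nxt = [b for a in frontier for b in adj[a] if b in subset and b not in reached]
            reached.update(nxt)
            frontier = nxt
        return len(reached) == len(subset)

    found = []
    for sign in (+1, -1):
        nodes = [e for e, t in sig.items() if np.sign(t) == sign]
        for size in range(len(nodes), min_size - 1, -1):
            for subset in itertools.combinations(sorted(nodes), size):
                if connected(subset) and not any(set(subset) <= set(f) for f in found):
                    # maximality: no significant same-sign neighbor outside
                    boundary = {b for a in subset for b in adj[a]} - set(subset)
                    if not (boundary & set(nodes)):
                        found.append(list(subset))
    return sorted(sorted(c) for c in found)
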