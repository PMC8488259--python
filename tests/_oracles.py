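"""Independent brute-force oracles used to cross-check the implementation.

Each oracle restates the operation's definition in the most literal way
possible (explicit enumeration, naive window scans, direct fixpoint
iteration) without sharing code with the package internals.
"""

import itertools

import numpy as np


def auc_pair_counting(scores, labels):
    """AUC as the literal fraction of (patient, control) pairs won."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for c in neg:
            if p > c:
                wins += 1.0
            elif p == c:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def idt_window_scan(ts, xs, ys, dispersion_px, min_duration_ms, gap_break_ms=200.0):
    """Exhaustive re-statement of dispersion-threshold fixation detection.

    Returns (start, end, cx, cy) tuples.  Dispersion of a window is
    (max x - min x) + (max y - min y); windows are grown greedily from the
    left, restarting one sample later when the minimum-duration window
    already exceeds the threshold; long gaps split the stream first.
    """
    ts, xs, ys = (np.asarray(a, dtype=float) for a in (ts, xs, ys))
    segments = []
    start = 0
    for i in range(1, len(ts)):
        if ts[i] - ts[i - 1] > gap_break_ms:
            segments.append((start, i))
            start = i
    segments.append((start, len(ts)))

    out = []
    for s, e in segments:
        i = s
        while i < e:
            j = None
            for cand in range(i, e):
                if ts[cand] - ts[i] >= min_duration_ms:
                    j = cand
                    break
            if j is None:
                break

            def disp(a, b):
                return (max(xs[a:b + 1]) - min(xs[a:b + 1])) + (
                    max(ys[a:b + 1]) - min(ys[a:b + 1])
                )

            if disp(i, j) <= dispersion_px:
                while j + 1 < e and disp(i, j + 1) <= dispersion_px:
                    j += 1
                out.append(
                    (ts[i], ts[j], float(np.mean(xs[i:j + 1])), float(np.mean(ys[i:j + 1])))
                )
                i = j + 1
            else:
                i += 1
    return out


def cfs_fixpoint(X, y, r_pair=0.85, r_label=0.2):
    """All elimination orders of the correlation-selection rule.

    First drops features with |label corr| < r_label, then repeatedly picks
    *any* remaining pair with |corr| >= r_pair and drops the lower-label-
    correlation member (earlier column kept on ties), branching over every
    possible pick order.  Returns the set of reachable terminal selections.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_feat = X.shape[1]

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    rlab = [abs(corr(X[:, i], y)) for i in range(n_feat)]
    alive = frozenset(i for i in range(n_feat) if rlab[i] >= r_label)
    pair_r = {
        (i, j): abs(corr(X[:, i], X[:, j]))
        for i, j in itertools.combinations(range(n_feat), 2)
    }

    results = set()

    def recurse(current):
        violating = [
            (i, j) for (i, j) in pair_r
            if i in current and j in current and pair_r[(i, j)] >= r_pair
        ]
        if not violating:
            results.add(current)
            return
        for i, j in violating:
            if rlab[i] < rlab[j] or (rlab[i] == rlab[j] and i > j):
                drop = i
            else:
                drop = j
            recurse(current - {drop})

    recurse(alive)
    return results


def transition_counts_path(aoi_path):
    """Literal transition counting over a sequence of AoI names."""
    counts = {}
    for a, b in zip(aoi_path[:-1], aoi_path[1:]):
        if a is None or b is None or a == b:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def reading_pass_oracle(word_path):
    """Direct recomputation of pass structure over word indices."""
    n = len(word_path)
    first_pass = []
    for pos in range(n):
        prior_max = max(word_path[:pos], default=-1)
        first_pass.append(word_path[pos] >= prior_max)
    regressions = [
        word_path[i] - word_path[i + 1]
        for i in range(n - 1)
        if word_path[i + 1] < word_path[i]
    ]
    rereading = sum(1 for i in range(n) if not first_pass[i])
    later_entries = 0
    for i in range(n):
        if not first_pass[i] and (i == 0 or word_path[i - 1] != word_path[i]):
            later_entries += 1
    refix = sum(1 for i in range(1, n) if word_path[i] == word_path[i - 1])
    multi = set()
    i = 0
    while i < n:
        j = i
        while j + 1 < n and word_path[j + 1] == word_path[i]:
            j += 1
        if j > i:
            multi.add(word_path[i])
        i = j + 1
    return {
        "first_pass_count": sum(first_pass),
        "rereading_count": rereading,
        "later_pass_entries": later_entries,
        "regression_amplitudes": regressions,
        "refixation_count": refix,
        "multi_fixation_words": multi,
    }


def tukey_pvalue(mean_i, mean_j, mse, n_per_group, k_groups, df_error):
    """Tukey HSD adjusted p-value from the studentized range distribution."""
    from scipy.stats import studentized_range

    q = abs(mean_i - mean_j) / np.sqrt(mse / n_per_group)
    return float(studentized_range.sf(q, k_groups, df_error))
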