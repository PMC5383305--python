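"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
recursion) and shares no code path with the package implementation.
"""

import itertools

from hadroclad.trees import Node, Tree


def all_rooted_topologies(labels):
    """All rooted-on-first-label topologies as nested tuples of labels."""
    first, rest = labels[0], labels[1:]

    def insertions(shape, item):
        yield (item, shape)
        if isinstance(shape, tuple):
            a, b = shape
            for s in insertions(a, item):
                yield (s, b)
            for s in insertions(b, item):
                yield (a, s)

    shapes = [rest[0]]
    for item in rest[1:]:
        shapes = [s for shape in shapes for s in insertions(shape, item)]
    return [(first, s) for s in shapes]


def shape_to_tree(shape):
    def rec(s):
        if not isinstance(s, tuple):
            return Node(s)
        node = Node()
        node.add_child(rec(s[0]))
        node.add_child(rec(s[1]))
        return node

    return Tree(rec(shape))


def column_state_sets(matrix, char_1based, alphabet):
    """Per-taxon allowed state sets for one character (missing = all)."""
    sets = {}
    for taxon in matrix.taxa:
        cell = matrix.cell(taxon, char_1based)
        if isinstance(cell, frozenset):
            sets[taxon] = set(cell)
        else:
            sets[taxon] = set(alphabet)
    return sets


def brute_force_char_steps(shape, allowed):
    """Exact minimum changes of one character on one topology.

    Enumerates every joint assignment of single states to internal nodes
    (tips range over their allowed sets) - feasible for tiny trees only.
    """
    tips = []
    internal_count = [0]

    def walk(s):
        if not isinstance(s, tuple):
            tips.append(s)
        else:
            internal_count[0] += 1
            walk(s[0])
            walk(s[1])

    walk(shape)
    alphabet = sorted(set().union(*[allowed[t] for t in tips]))
    best = [float("inf")]

    def cost(s, state):
        if not isinstance(s, tuple):
            return 0 if state in allowed[s] else float("inf")
        out = float("inf")
        for child_states in itertools.product(alphabet, repeat=2):
            c = sum(
                cost(sub, cs) + (cs != state)
                for sub, cs in zip(s, child_states)
            )
            out = min(out, c)
        return out

    return min(cost(shape, a) for a in alphabet)


def brute_force_fitch(matrix, shape):
    """Exact tree length: sum of per-character brute-force minima."""
    total = 0
    per_char = []
    for c in range(1, matrix.n_char + 1):
        observed = set()
        for taxon in matrix.taxa:
            cell = matrix.cell(taxon, c)
            if isinstance(cell, frozenset):
                observed |= cell
        alphabet = sorted(observed) or ["0"]
        allowed = column_state_sets(matrix, c, alphabet)
        steps = brute_force_char_steps(shape, allowed)
        per_char.append(steps)
        total += steps
    return total, per_char


def brute_force_best_trees(matrix, outgroup):
    """Exact best length and optimal topology set over all rooted trees."""
    labels = [outgroup] + [t for t in matrix.taxa if t != outgroup]
    best = None
    optimal = []
    for shape in all_rooted_topologies(labels):
        total, _ = brute_force_fitch(matrix, shape)
        if best is None or total < best:
            best, optimal = total, [shape]
        elif total == best:
            optimal.append(shape)
    return best, optimal


def brute_force_min_max_steps(column_cells, taxa):
    """Exact min/max Fitch steps of one column over all topologies."""
    observed = set()
    for cell in column_cells:
        if isinstance(cell, frozenset):
            observed |= cell
    alphabet = sorted(observed) or ["0"]
    allowed = {
        t: (set(cell) if isinstance(cell, frozenset) else set(alphabet))
        for t, cell in zip(taxa, column_cells)
    }
    lo, hi = float("inf"), 0
    for shape in all_rooted_topologies(list(taxa)):
        steps = brute_force_char_steps(shape, allowed)
        lo, hi = min(lo, steps), max(hi, steps)
    return lo, hi


def brute_force_unambiguous_changes(matrix, shape):
    """Per-clade unambiguous changes by enumerating all optimal labelings.

    Returns {frozenset(clade tips): {(char, derived_state), ...}} keeping
    only changes present with one fixed derived state in every optimal
    joint reconstruction.
    """
    nodes = []

    def walk(s):
        nodes.append(s)
        if isinstance(s, tuple):
            walk(s[0])
            walk(s[1])

    walk(shape)
    internals = [s for s in nodes if isinstance(s, tuple)]

    def leaves(s):
        if not isinstance(s, tuple):
            return [s]
        return leaves(s[0]) + leaves(s[1])

    result = {}
    for c in range(1, matrix.n_char + 1):
        observed = set()
        for taxon in matrix.taxa:
            cell = matrix.cell(taxon, c)
            if isinstance(cell, frozenset):
                observed |= cell
        alphabet = sorted(observed) or ["0"]
        allowed = column_state_sets(matrix, c, alphabet)
        # enumerate all assignments (internal x alphabet, tips x allowed)
        tips = [s for s in nodes if not isinstance(s, tuple)]
        best = None
        optimal_assignments = []
        for internal_states in itertools.product(alphabet, repeat=len(internals)):
            imap = dict(zip(map(id, internals), internal_states))
            for tip_states in itertools.product(*[sorted(allowed[t]) for t in tips]):
                tmap = dict(zip(tips, tip_states))

                def state(s):
                    return imap[id(s)] if isinstance(s, tuple) else tmap[s]

                cost = 0
                for s in internals:
                    for child in s:
                        cost += state(child) != state(s)
                if best is None or cost < best:
                    best, optimal_assignments = cost, []
                if cost == best:
                    optimal_assignments.append(
                        {**{id(s): imap[id(s)] for s in internals}, **
                         {t: tmap[t] for t in tips}}
                    )
        # per edge (above each non-root node) collect (parent, child) pairs
        for s in internals:
            for child in s:
                key = frozenset(leaves(child))
                pairs = set()
                for asg in optimal_assignments:
                    p = asg[id(s)]
                    ch = asg[id(child)] if isinstance(child, tuple) else asg[child]
                    pairs.add((p, ch))
                if pairs and all(p != ch for p, ch in pairs):
                    derived = {ch for _, ch in pairs}
                    if len(derived) == 1:
                        result.setdefault(key, set()).add((c, derived.pop()))
    return result
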