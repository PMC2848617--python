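"""Independent brute-force oracle for the averaged one-dependence formula.

Deliberately naive: pure-Python dict scans that materialize every
one-dependence estimator explicitly.  Shares no code with appia.aode.

Rows are dicts attribute -> value (or None for missing); value domains are
given explicitly so smoothing denominators are unambiguous.
"""

from __future__ import annotations


def _count(rows, labels, predicate):
    return sum(1 for row, label in zip(rows, labels) if predicate(row, label))


def nb_oracle(rows, labels, n_values, instance):
    """Zero-dependence posterior with joint-based smoothing."""
    classes = sorted(set(labels))
    K = len(classes)
    N = len(rows)
    attrs = list(n_values)
    known = [a for a in attrs if instance.get(a) is not None]
    scores = {}
    for y in classes:
        n_y = _count(rows, labels, lambda r, l: l == y)
        p_y = (n_y + 1) / (N + K)
        s = p_y
        for a in known:
            n_a = _count(rows, labels, lambda r, l: r.get(a) is not None)
            n_y_xa = _count(
                rows, labels, lambda r, l: l == y and r.get(a) == instance[a]
            )
            p_joint = (n_y_xa + 1) / (n_a + K * n_values[a])
            s *= p_joint / p_y
        scores[y] = s
    total = sum(scores.values())
    return {y: s / total for y, s in scores.items()}


def aode_oracle(rows, labels, n_values, instance, m=1):
    """Averaged one-dependence posterior, each estimator expanded in full."""
    classes = sorted(set(labels))
    K = len(classes)
    attrs = list(n_values)
    known = [a for a in attrs if instance.get(a) is not None]
    scores = {}
    for y in classes:
        s = 0.0
        for a in known:
            frequency = _count(
                rows, labels, lambda r, l: r.get(a) == instance[a]
            )
            if frequency < m:
                continue
            n_a = _count(rows, labels, lambda r, l: r.get(a) is not None)
            n_y_xa = _count(
                rows, labels, lambda r, l: l == y and r.get(a) == instance[a]
            )
            term = (n_y_xa + 1) / (n_a + K * n_values[a])
            for b in attrs:  # implementation order: attribute index ascending
                if b == a or instance.get(b) is None:
                    continue
                n_ab = _count(
                    rows,
                    labels,
                    lambda r, l: l == y
                    and r.get(a) == instance[a]
                    and r.get(b) == instance[b],
                )
                term *= (n_ab + 1) / (n_y_xa + n_values[b])
            s += term
        scores[y] = s
    if all(v == 0.0 for v in scores.values()):
        return nb_oracle(rows, labels, n_values, instance)
    total = sum(scores.values())
    return {y: s / total for y, s in scores.items()}
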