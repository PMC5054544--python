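"""Independent brute-force oracles shared by the unit and acceptance tests.

Each function recomputes a quantity by exhaustive enumeration, staying
independent of the implementation path it checks.
"""

from cidex.corpus_io import Document
from cidex.edg import EDG, EdgEdge, collapse_parallel_edges
from cidex.linguistic import ParseRecord, attach_parse, split_sentences


def dummy_edg(n, edges):
    """EDG over n one-letter tokens with the given (src, tgt, label, layer)."""
    text = " ".join(chr(97 + i) for i in range(n))
    doc = Document("1", text, "")
    split_sentences(doc)
    rec = ParseRecord([(chr(97 + i), chr(97 + i), "NN") for i in range(n)],
                      [-1] * n, ["root"] * n)
    attach_parse(doc.sentences[0], rec, doc.text)
    edg = EDG(doc.sentences[0])
    for s, t, label, layer in edges:
        edg.add_edge(EdgEdge(s, t, label, layer))
    return edg


def brute_force_paths(edg, a, b):
    """Exhaustive DFS enumeration of all minimal simple paths over the
    collapsed edge set, as (source, target, label, direction) step tuples."""
    adj = {}
    for e in collapse_parallel_edges(edg.edges):
        adj.setdefault(e.source, []).append((e.target, e, +1))
        adj.setdefault(e.target, []).append((e.source, e, -1))
    paths = []

    def dfs(v, seen, steps):
        if v == b:
            paths.append(tuple(steps))
            return
        for (w, e, d) in adj.get(v, []):
            if w not in seen:
                dfs(w, seen | {w}, steps + [(e.source, e.target, e.label, d)])

    dfs(a, {a}, [])
    if not paths:
        return set()
    shortest = min(len(p) for p in paths)
    return {p for p in paths if len(p) == shortest}


def window_oracle(doc, mention, radius):
    """Brute-force bag-of-words window: for each occurrence of the concept
    ID, take the word tokens of its sentence, cut out the mention tokens,
    slice radius each side."""
    bag = {}
    for m in doc.mentions:
        if m.etype != mention.etype or \
                not set(m.concept_ids) & set(mention.concept_ids):
            continue
        sent = next(s for s in doc.sentences
                    if m.start >= s.start and m.end <= s.end)
        words = [t for t in sent.tokens if any(c.isalnum() for c in t.text)]
        inside = [i for i, t in enumerate(words)
                  if t.start < m.end and t.end > m.start]
        if not inside:
            continue
        lo, hi = min(inside), max(inside)
        ctx = words[max(0, lo - radius):lo] + words[hi + 1:hi + 1 + radius]
        for t in ctx:
            key = f"bow:{t.lemma.lower()}"
            bag[key] = bag.get(key, 0.0) + 1
    return bag
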