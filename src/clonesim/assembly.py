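"""Homology assembly simulation in three steps.

1. **Homology search** -- every pair of fragments (and each fragment
   against the reverse complement of its partners) is scanned for shared
   subsequences of at least ``limit`` (default 25) nucleotides.  The scan
   uses a suffix array built with the linear-time skew (DC3) algorithm of
   Karkkainen & Sanders plus Kasai's LCP construction, so it stays fast on
   plasmid-scale sequences.  Detected overlaps are recorded as features on
   the fragments for graphical inspection.

2. **Graph construction** -- a directed multigraph where each distinct
   overlap sequence is a node and the intervening stretches of each
   fragment are edges.  Two terminal nodes, 5' and 3', bracket every
   fragment so both linear and circular recombination products can be
   traced.  Fragments enter the graph in both orientations.

3. **Product tracing** -- linear products are all simple 5'->3' paths;
   circular products are simple cycles, and cycles that share a node are
   additionally composed (one turn of each circular subgraph) so the
   largest possible product is always reported.  Products are deduplicated
   by canonical form and sorted by descending span.

The model joins fragments on exact sequence identity only, which is how
both in-vivo homologous recombination (single-strand annealing) and
Gibson assembly resolve at the sequence level; neither efficiency nor
junction chemistry is modelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .duplex import reverse_complement
from .errors import TopologyError
from .record import AnnotatedMolecule, Feature

DEFAULT_LIMIT = 25
FIVE = "5'"
THREE = "3'"


# ---------------------------------------------------------------------------
# Step 0: suffix array machinery
# ---------------------------------------------------------------------------

def _radix_pass(a, b, r, n, K):
    """Stable counting sort of ``a[:n]`` into ``b`` by key ``r[a[i]]``."""
    count = [0] * (K + 1)
    for i in range(n):
        count[r[a[i]]] += 1
    total = 0
    for i in range(K + 1):
        count[i], total = total, total + count[i]
    for i in range(n):
        key = r[a[i]]
        b[count[key]] = a[i]
        count[key] += 1


def _leq2(a1, a2, b1, b2):
    return a1 < b1 or (a1 == b1 and a2 <= b2)


def _leq3(a1, a2, a3, b1, b2, b3):
    return a1 < b1 or (a1 == b1 and _leq2(a2, a3, b2, b3))


def _skew(s, sa, n, K):
    """Karkkainen-Sanders skew (DC3) algorithm.

    ``s`` is an integer sequence of length >= n+3 with values in 1..K and
    three trailing zeros; the suffix array of ``s[:n]`` is written into
    ``sa[:n]``.
    """
    n0 = (n + 2) // 3
    n1 = (n + 1) // 3
    n2 = n // 3
    n02 = n0 + n2
    s12 = [0] * (n02 + 3)
    sa12 = [0] * (n02 + 3)
    j = 0
    for i in range(n + (n0 - n1)):
        if i % 3:
            s12[j] = i
            j += 1
    # radix sort the mod-1/mod-2 triples
    _radix_pass(s12, sa12, s[2:] + [0], n02, K)
    _radix_pass(sa12, s12, s[1:] + [0], n02, K)
    _radix_pass(s12, sa12, s, n02, K)
    # lexicographic names for the triples
    name, c0, c1, c2 = 0, -1, -1, -1
    for i in range(n02):
        p = sa12[i]
        if s[p] != c0 or s[p + 1] != c1 or s[p + 2] != c2:
            name += 1
            c0, c1, c2 = s[p], s[p + 1], s[p + 2]
        if p % 3 == 1:
            s12[p // 3] = name
        else:
            s12[p // 3 + n0] = name
    if name < n02:  # names not yet unique: recurse
        _skew(s12[:n02] + [0, 0, 0], sa12, n02, name)
        for i in range(n02):
            s12[sa12[i]] = i + 1
    else:
        for i in range(n02):
            sa12[s12[i] - 1] = i
    # sort the mod-0 suffixes by (first char, rank of rest)
    s0 = [3 * sa12[i] for i in range(n02) if sa12[i] < n0]
    sa0 = [0] * n0
    _radix_pass(s0, sa0, s, n0, K)
    # merge
    p = 0
    t = n0 - n1
    k = 0
    while k < n:
        i = sa12[t] * 3 + 1 if sa12[t] < n0 else (sa12[t] - n0) * 3 + 2
        jj = sa0[p]
        if (sa12[t] < n0 and _leq2(s[i], s12[sa12[t] + n0], s[jj], s12[jj // 3])) or \
           (sa12[t] >= n0 and _leq3(s[i], s[i + 1], s12[sa12[t] - n0 + 1],
                                    s[jj], s[jj + 1], s12[jj // 3 + n0])):
            sa[k] = i
            t += 1
            if t == n02:
                k += 1
                while p < n0:
                    sa[k] = sa0[p]
                    p += 1
                    k += 1
                break
        else:
            sa[k] = jj
            p += 1
            if p == n0:
                k += 1
                while t < n02:
                    sa[k] = sa12[t] * 3 + 1 if sa12[t] < n0 else (sa12[t] - n0) * 3 + 2
                    t += 1
                    k += 1
                break
        k += 1


def suffix_array(s):
    """Suffix array of ``s`` by the linear-time skew (DC3) construction.

    Accepts a string or a sequence of non-negative integers; returns the
    starting positions of the suffixes in lexicographic order.
    """
    if isinstance(s, str):
        arr = [ord(c) for c in s]
    else:
        arr = list(s)
    n = len(arr)
    if n == 0:
        return []
    if n == 1:
        return [0]
    # compact the alphabet to 1..K (DC3 reserves 0 for padding)
    ranks = {v: i + 1 for i, v in enumerate(sorted(set(arr)))}
    arr = [ranks[v] for v in arr]
    if n == 2:
        # on a tie the shorter suffix sorts first
        return [0, 1] if arr[0] < arr[1] else [1, 0]
    sa = [0] * n
    _skew(arr + [0, 0, 0], sa, n, len(ranks))
    return sa


def lcp_array(s, sa):
    """Kasai LCP array: ``lcp[i]`` = LCP of suffixes ``sa[i-1]`` and ``sa[i]``."""
    n = len(sa)
    rank = [0] * n
    for i, p in enumerate(sa):
        rank[p] = i
    lcp = [0] * n
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and s[i + h] == s[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


# ---------------------------------------------------------------------------
# Step 1: shared homologies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapMatch:
    """A maximal shared substring of length >= limit between two strings."""

    start_a: int
    start_b: int
    length: int
    sequence: str
    frag_a: int = 0
    frag_b: int = 1


def common_substrings(a: str, b: str, limit: int):
    """All maximal shared substrings of length >= ``limit``.

    Found via the suffix array of ``a + SEP + b`` with LCP information.
    A reported match is maximal: it cannot be extended in either
    direction, and matches wholly contained in a longer reported match on
    the same diagonal are not repeated.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    if not a or not b:
        return []
    sep = "\x01"
    s = a + sep + b
    sa = suffix_array(s)
    lcp = lcp_array(s, sa)
    la = len(a)

    matches = []
    n = len(sa)
    i = 0
    while i < n:
        # maximal block of suffixes pairwise sharing >= limit prefix
        j = i + 1
        while j < n and lcp[j] >= limit:
            j += 1
        if j - i > 1:
            block = sa[i:j]
            blocklcp = lcp[i + 1:j]  # lcp between consecutive block members
            for r2 in range(1, len(block)):
                ell = None
                for r1 in range(r2 - 1, -1, -1):
                    step = blocklcp[r1]
                    ell = step if ell is None else min(ell, step)
                    if ell < limit:
                        break
                    p, q = block[r1], block[r2]
                    if (p < la) == (q < la):
                        continue  # same string
                    apos, bpos = (p, q - la - 1) if p < la else (q, p - la - 1)
                    if apos > 0 and bpos > 0 and a[apos - 1] == b[bpos - 1]:
                        continue  # extendable left: not maximal
                    matches.append(OverlapMatch(apos, bpos, ell, a[apos:apos + ell]))
        i = j
    matches.sort(key=lambda m: (m.start_a, m.start_b))
    return matches


def _pair_matches(fragments, limit, internal_overlaps):
    """Matches for every oriented fragment pair.

    Returns ``{(i, 1, j, oj): [OverlapMatch, ...]}`` for every pair
    i < j and both relative orientations of the partner (oj = +1: as
    given, -1: its reverse complement).  Only relative orientation
    matters for homology, so fragment i is always read in its given
    orientation.  With ``internal_overlaps`` false, only matches that lie
    at a terminus of both fragments are kept (the classic
    terminal-homology situation of designed assemblies).
    """
    seqs = {}
    for i, f in enumerate(fragments):
        fill = f.fill()
        seqs[(i, 1)] = fill
        seqs[(i, -1)] = reverse_complement(fill)
    out = {}
    for i in range(len(fragments)):
        for j in range(i + 1, len(fragments)):
            for oj in (1, -1):
                a, b = seqs[(i, 1)], seqs[(j, oj)]
                ms = common_substrings(a, b, limit)
                if not internal_overlaps:
                    ms = [m for m in ms
                          if (m.start_a == 0 or m.start_a + m.length == len(a))
                          and (m.start_b == 0 or m.start_b + m.length == len(b))]
                out[(i, 1, j, oj)] = [
                    OverlapMatch(m.start_a, m.start_b, m.length, m.sequence,
                                 i, j)
                    for m in ms]
    return out


def annotate_overlaps(fragments, limit: int = DEFAULT_LIMIT,
                      internal_overlaps: bool = True):
    """Record every shared homology as a feature on each fragment.

    Each fragment is compared with every partner and with the partner's
    reverse complement; detected regions become ``overlap`` features (on
    the minus strand when the region matches a partner's reverse
    complement), so the homologies can be inspected in a sequence editor.
    Returns annotated copies; the inputs are not modified.
    """
    annotated = [f.copy() for f in fragments]
    matches = _pair_matches(fragments, limit, internal_overlaps)
    seen = [set() for _ in fragments]

    def _add(idx, orient, start, length, partner):
        span = fragments[idx].span
        if orient == 1:
            s, strand = start, 1
        else:  # position was on the reverse complement
            s, strand = span - start - length, -1
        key = (s, length, strand)
        if key in seen[idx]:
            return
        seen[idx].add(key)
        annotated[idx].features.append(Feature(
            "overlap", s, s + length, strand,
            {"note": [f"{length} bp homology with {fragments[partner].id}"]}))

    for (i, oi, j, oj), ms in matches.items():
        for m in ms:
            _add(i, oi, m.start_a, m.length, j)
            _add(j, oj, m.start_b, m.length, i)
    return annotated


@dataclass
class AssemblyGraph:
    """Overlap graph: nodes are overlap sequences plus 5'/3' terminals."""

    graph: nx.MultiDiGraph
    fragments: list
    limit: int
    internal_overlaps: bool

    @property
    def overlap_nodes(self):
        return [n for n in self.graph.nodes if n not in (FIVE, THREE)]


def build_graph(fragments, limit: int = DEFAULT_LIMIT,
                internal_overlaps: bool = True) -> AssemblyGraph:
    """Second assembly step: overlap nodes, intervening-sequence edges.

    Every fragment is inserted in both orientations; each oriented
    fragment contributes edges from the 5' terminal through its overlap
    occurrences (in positional order, every non-overlapping ordered pair)
    to the 3' terminal.  Edge data carry the fragment index, orientation
    and the intervening sequence between the two overlap occurrences.
    """
    matches = _pair_matches(fragments, limit, internal_overlaps)
    # occurrence lists per oriented fragment: {(i, o): {(pos, node_seq)}}
    occs = {}
    for i in range(len(fragments)):
        for o in (1, -1):
            occs[(i, o)] = set()
    span = {i: fragments[i].span for i in range(len(fragments))}
    for (i, oi, j, oj), ms in matches.items():
        for m in ms:
            # the same physical region seen from the other orientation
            rcseq = reverse_complement(m.sequence)
            occs[(i, oi)].add((m.start_a, m.sequence))
            occs[(i, -oi)].add((span[i] - m.start_a - m.length, rcseq))
            occs[(j, oj)].add((m.start_b, m.sequence))
            occs[(j, -oj)].add((span[j] - m.start_b - m.length, rcseq))

    g = nx.MultiDiGraph()
    g.add_node(FIVE)
    g.add_node(THREE)
    for (i, o), occset in sorted(occs.items()):
        seq = fragments[i].fill()
        if o == -1:
            seq = reverse_complement(seq)
        olist = sorted(occset)
        for pos, node in olist:
            g.add_edge(FIVE, node, fragment=i, orientation=o,
                       piece=seq[:pos], u_pos=None, window=(0, pos))
            g.add_edge(node, THREE, fragment=i, orientation=o,
                       piece=seq[pos + len(node):], u_pos=pos,
                       window=(pos, len(seq)))
        for (pa, na), (pb, nb) in itertools.combinations(olist, 2):
            if pb >= pa + len(na):
                g.add_edge(na, nb, fragment=i, orientation=o,
                           piece=seq[pa + len(na):pb], u_pos=pa,
                           window=(pa, pb))
    return AssemblyGraph(g, list(fragments), limit, internal_overlaps)


# ---------------------------------------------------------------------------
# Step 3: tracing products
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    """One assembled product and how it was put together."""

    path: list            # [(fragment id, orientation, overlap-to-next), ...]
    circular: bool
    molecule: AnnotatedMolecule
    fragment_spans: dict = field(default_factory=dict)  # fragment id -> span

    @property
    def span(self) -> int:
        return self.molecule.span

    def figure(self) -> str:
        """Monospace diagram of the fragment chain and its junctions.

        One line per fragment (id and span tag), one ``|nn`` line per
        junction giving the overlap length; circular contigs close with an
        explicit wrap-around line.
        """
        lines = []
        for frag_id, orient, olen in self.path:
            arrow = "" if orient == 1 else " (rc)"
            lines.append(f"{frag_id}{arrow}  -{self.fragment_spans.get(frag_id, '?')}")
            if olen is not None:
                lines.append(f"  |{olen}")
        if self.circular:
            lines.append(f"  --> back to {self.path[0][0]} (circular, "
                         f"{self.molecule.short_repr()})")
        return "\n".join(lines)

    def __repr__(self) -> str:
        tag = "o" if self.circular else "-"
        return f"Contig({tag}{self.span}: " + \
            "|".join(str(p[0]) for p in self.path) + ")"


@dataclass
class AssemblyResult:
    """Everything the three-step assembly produced."""

    fragments: list
    limit: int
    internal_overlaps: bool
    graph: AssemblyGraph
    linear_products: list = field(default_factory=list)
    circular_products: list = field(default_factory=list)
    sharing_homology: int = 0

    def report(self) -> str:
        frags = " ".join(f.short_repr() for f in self.fragments)
        lin = " ".join(c.molecule.short_repr() for c in self.linear_products)
        circ = " ".join(c.molecule.short_repr() for c in self.circular_products)
        return "\n".join([
            "Assembly",
            f"fragments analyzed...: {len(self.fragments)} [{frags}]",
            f"sharing homology.....: {self.sharing_homology}",
            f"homology limit {self.limit} bp",
            "internal overlaps....: "
            + ("considered" if self.internal_overlaps else "terminal only"),
            f"linear products......: {len(self.linear_products)} [{lin}]",
            f"circular products....: {len(self.circular_products)} [{circ}]",
        ])

    def __repr__(self) -> str:
        return self.report()


def _edge_runs(edges):
    """Group consecutive edges by (fragment, orientation)."""
    runs = []
    for u, v, d in edges:
        key = (d["fragment"], d["orientation"])
        if not runs or runs[-1][0] != key:
            runs.append((key, [(u, v, d)]))
        else:
            runs[-1][1].append((u, v, d))
    return runs


def _valid_walk(edges, circular):
    """A walk is realizable iff no fragment is used more than once."""
    runs = _edge_runs(edges)
    if circular and len(runs) > 1 and runs[0][0] == runs[-1][0]:
        # wrap-around: first and last run belong to the same oriented use
        runs = [(runs[-1][0], runs[-1][1] + runs[0][1])] + runs[1:-1]
    frags = [key[0] for key, _ in runs]
    return len(frags) == len(set(frags)), runs


def _stitch(edges, circular, oriented):
    """Sequence and carried-over features of a walk.

    ``oriented[(i, o)]`` holds (filled sequence, feature list) of fragment
    ``i`` in orientation ``o``.  Linear walks run 5' -> ... -> 3'; circular
    walks are a closed edge cycle starting at any overlap node.
    """
    parts = []
    feats = []
    pos = 0
    for u, v, d in edges:
        key = (d["fragment"], d["orientation"])
        _, frag_feats, frag_span = oriented[key]
        w0, w1 = d["window"]
        if u == FIVE:
            seg = d["piece"] + (v if v != THREE else "")
            offset = pos  # window starts at fragment coord 0
            win = (0, w1 + (len(v) if v != THREE else 0))
        elif circular or u != FIVE:
            # window includes the source node u
            seg = (u + d["piece"]) if circular else d["piece"] + (v if v != THREE else "")
            if circular:
                offset = pos
                win = (d["u_pos"], w1)
            else:
                offset = pos - len(u)
                win = (d["u_pos"], w1 + (len(v) if v != THREE else 0))
        from .record import features_in_window
        for f in features_in_window(frag_feats, win[0], win[1] - win[0],
                                    frag_span, False):
            f.start += offset
            f.end += offset
            feats.append(f)
        parts.append(seg)
        pos += len(seg)
    return "".join(parts), feats


def _walk_contig(edges, circular, fragments, oriented):
    ok, runs = _valid_walk(edges, circular)
    if not ok:
        return None
    seq, feats = _stitch(edges, circular, oriented)
    if circular and not seq:
        return None
    path = []
    for idx, (key, run_edges) in enumerate(runs):
        frag = fragments[key[0]]
        last_v = run_edges[-1][1]
        if circular:
            olen = len(last_v)
        else:
            olen = len(last_v) if idx < len(runs) - 1 else None
        path.append((frag.id, key[1], olen))
    feats = [f for f in feats if f.end <= len(seq)]
    mol = AnnotatedMolecule.from_string(seq, circular=circular,
                                        id="assembly_" + ("o" if circular else "-")
                                        + str(len(seq)))
    mol.features = feats
    mol._validate_features()
    contig = Contig(path, circular, mol,
                    {fragments[i].id: fragments[i].span
                     for i in {k[0] for k, _ in runs}})
    return contig


def _expanded_cycles(g):
    """Edge-level simple cycles of the overlap-node subgraph."""
    sub = g.subgraph(n for n in g.nodes if n not in (FIVE, THREE))
    out = []
    for node_cycle in nx.simple_cycles(sub):
        k = len(node_cycle)
        choices = []
        for a in range(k):
            u, v = node_cycle[a], node_cycle[(a + 1) % k]
            keys = sorted(sub[u][v]) if sub.has_edge(u, v) else []
            choices.append([(u, v, sub[u][v][key]) for key in keys])
        if not all(choices):
            continue
        for combo in itertools.product(*choices):
            out.append(list(combo))
    return out


def _rotate_cycle(walk, node):
    """Rotate a closed edge walk to start at ``node``."""
    for i, (u, v, d) in enumerate(walk):
        if u == node:
            return walk[i:] + walk[:i]
    raise ValueError("node not on cycle")


def _compose(cycles, max_products):
    """One-turn compositions of node-sharing, fragment-disjoint cycles.

    Each simple cycle may be traversed at most once inside a product; two
    cycles sharing an overlap node combine into one larger circular walk,
    which is how the largest possible product arises from nested circular
    subgraphs.
    """
    items = []
    for c in cycles:
        frags = frozenset(d["fragment"] for _, _, d in c)
        nodes = frozenset(u for u, _, _ in c)
        items.append((c, frags, nodes))
    walks = [(c, frags, nodes, frozenset([i]))
             for i, (c, frags, nodes) in enumerate(items)]
    queue = list(walks)
    while queue and len(walks) < max_products:
        walk, wfrags, wnodes, used = queue.pop(0)
        for i, (c, cfrags, cnodes) in enumerate(items):
            if i in used or (wfrags & cfrags):
                continue
            shared = sorted(wnodes & cnodes)
            for node in shared:
                spliced = []
                for j, (u, v, d) in enumerate(walk):
                    if u == node and not spliced:
                        spliced = walk[:j] + _rotate_cycle(c, node) + walk[j:]
                if spliced:
                    entry = (spliced, wfrags | cfrags, wnodes | cnodes,
                             used | {i})
                    walks.append(entry)
                    queue.append(entry)
                    if len(walks) >= max_products:
                        break
            if len(walks) >= max_products:
                break
    return [w[0] for w in walks]


def assemble(fragments, limit: int = DEFAULT_LIMIT,
             internal_overlaps: bool = True,
             max_circular: int = 50, max_linear: int = 500) -> AssemblyResult:
    """Run the three-step assembly and trace every product.

    Linear products are all simple 5'->3' paths through the overlap graph
    (a fragment may participate only once per product); circular products
    are simple cycles plus one-turn compositions of node-sharing cycles.
    Products are deduplicated by canonical form and returned sorted by
    descending span.  ``max_linear``/``max_circular`` bound the
    enumeration on pathological graphs.
    """
    fragments = list(fragments)
    for f in fragments:
        if f.circular:
            raise TopologyError(f"assemble() expects linear fragments; "
                                f"{f.id} is circular")
    annotated = annotate_overlaps(fragments, limit, internal_overlaps)
    ag = build_graph(fragments, limit, internal_overlaps)
    g = ag.graph

    oriented = {}
    for i, f in enumerate(annotated):
        rc = f.reverse_complement()
        oriented[(i, 1)] = (f.fill(), f.features, f.span)
        oriented[(i, -1)] = (rc.fill(), rc.features, rc.span)

    sharing = {d["fragment"] for _, _, d in g.edges(data=True)}

    linear = {}
    count = 0
    for keyed_path in nx.all_simple_edge_paths(g, FIVE, THREE):
        if count >= max_linear:
            break
        edges = [(u, v, g[u][v][k]) for u, v, k in keyed_path]
        contig = _walk_contig(edges, False, annotated, oriented)
        if contig is None:
            continue
        count += 1
        key = contig.molecule.canonical_form()
        if key not in linear:
            linear[key] = contig

    circular = {}
    cycles = [c for c in _expanded_cycles(g)
              if _valid_walk(c, True)[0]]
    for walk in _compose(cycles, max_circular):
        contig = _walk_contig(walk, True, annotated, oriented)
        if contig is None:
            continue
        key = contig.molecule.canonical_form()
        if key not in circular:
            circular[key] = contig

    lin = sorted(linear.values(), key=lambda c: (-c.span, c.molecule.canonical_form()))
    circ = sorted(circular.values(), key=lambda c: (-c.span, c.molecule.canonical_form()))
    return AssemblyResult(annotated, limit, internal_overlaps, ag,
                          lin, circ, len(sharing))
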