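"""Assembly: suffix arrays, homology search, graph, product enumeration."""

import itertools
import re

import pytest

from clonesim.assembly import (annotate_overlaps, assemble, build_graph,
                               common_substrings, lcp_array, suffix_array)
from clonesim.duplex import reverse_complement
from clonesim.errors import TopologyError
from clonesim.record import AnnotatedMolecule
from clonesim.synthetic import figure_eight_set, overlapping_fragments
from tests.conftest import make_dna


class TestSuffixArray:
    def test_known_examples(self):
        assert suffix_array("banana") == [5, 3, 1, 0, 4, 2]
        assert suffix_array("aaaa") == [3, 2, 1, 0]
        assert suffix_array("") == []
        assert suffix_array("z") == [0]

    def test_random_strings_match_naive_oracle(self, rng):
        for trial in range(200):
            n = rng.randint(0, 60) if trial < 150 else rng.randint(500, 1000)
            alpha = "ACGT" if trial % 2 else "AC"
            s = "".join(rng.choice(alpha) for _ in range(n))
            assert suffix_array(s) == sorted(range(n), key=lambda i: s[i:])

    def test_lcp_against_direct_comparison(self, rng):
        s = make_dna(rng, 400)
        sa = suffix_array(s)
        lcp = lcp_array(s, sa)
        for r in range(1, len(s)):
            a, b = s[sa[r - 1]:], s[sa[r]:]
            direct = next((k for k, (x, y) in enumerate(zip(a, b)) if x != y),
                          min(len(a), len(b)))
            assert lcp[r] == direct


def dp_matches(a, b, limit):
    """O(n*m) dynamic-programming maximal-match oracle."""
    M = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                M[i][j] = M[i - 1][j - 1] + 1
    out = []
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            ln = M[i][j]
            if ln >= limit and (i == len(a) or j == len(b)
                                or a[i] != b[j]):
                out.append((i - ln, j - ln, ln))
    return sorted(out)


class TestCommonSubstrings:
    def test_single_planted_overlap(self, rng):
        ov = make_dna(rng, 30)
        a = make_dna(rng, 60) + ov + make_dna(rng, 40)
        b = make_dna(rng, 20) + ov + make_dna(rng, 80)
        ms = common_substrings(a, b, 25)
        planted = [m for m in ms if m.length >= 30]
        assert len(planted) == 1 and planted[0].sequence == ov

    def test_identical_strings_full_match(self, rng):
        s = make_dna(rng, 70)
        ms = common_substrings(s, s, 25)
        assert any(m.start_a == 0 and m.start_b == 0 and m.length == 70
                   for m in ms)

    def test_matches_equal_dp_oracle(self, rng):
        for _ in range(60):
            a = make_dna(rng, rng.randint(50, 300))
            b = make_dna(rng, rng.randint(50, 300))
            if rng.random() < 0.8:
                ov = make_dna(rng, rng.randint(15, 40))
                pa = rng.randint(0, len(a) - len(ov))
                pb = rng.randint(0, len(b) - len(ov))
                a = a[:pa] + ov + a[pa + len(ov):]
                b = b[:pb] + ov + b[pb + len(ov):]
            got = sorted((m.start_a, m.start_b, m.length)
                         for m in common_substrings(a, b, 15))
            assert got == dp_matches(a, b, 15)


class TestAnnotateOverlaps:
    def test_designed_terminal_overlaps(self, rng):
        frags = overlapping_fragments(3, (150, 250), 30,
                                      circular_closure=True, seed=11)
        annotated = annotate_overlaps(frags, limit=25)
        for f in annotated:
            olaps = [x for x in f.features if x.kind == "overlap"]
            assert len(olaps) == 2

    def test_no_overlap_no_feature(self, rng):
        a = AnnotatedMolecule.from_string(make_dna(rng, 200), id="a")
        b = AnnotatedMolecule.from_string(make_dna(rng, 200), id="b")
        for f in annotate_overlaps([a, b], limit=25):
            assert [x for x in f.features if x.kind == "overlap"] == []

    def test_reverse_complement_partner_annotated(self, rng):
        ov = make_dna(rng, 28)
        a = AnnotatedMolecule.from_string(make_dna(rng, 100) + ov, id="a")
        b = AnnotatedMolecule.from_string(
            reverse_complement(make_dna(rng, 90) + ov), id="b")
        annotated = annotate_overlaps([a, b], limit=25)
        fa = [x for x in annotated[0].features if x.kind == "overlap"]
        fb = [x for x in annotated[1].features if x.kind == "overlap"]
        assert len(fa) == 1 and len(fb) == 1
        assert fa[0].strand != fb[0].strand
        assert (fa[0].start, fa[0].end) == (100, 128)
        assert (fb[0].start, fb[0].end) == (0, 28)


class TestBuildGraph:
    def test_three_fragment_cycle_topology(self):
        frags = overlapping_fragments(3, (150, 250), 30,
                                      circular_closure=True, seed=3)
        ag = build_graph(frags, limit=25)
        assert len(ag.overlap_nodes) == 6  # 3 junctions x 2 orientations
        import networkx as nx
        sub = ag.graph.subgraph(ag.overlap_nodes)
        cycles = list(nx.simple_cycles(sub))
        assert len(cycles) == 2  # the designed circle, seen from both faces

    def test_no_overlap_graph_only_terminal_paths(self, rng):
        a = AnnotatedMolecule.from_string(make_dna(rng, 150), id="a")
        b = AnnotatedMolecule.from_string(make_dna(rng, 150), id="b")
        ag = build_graph([a, b], limit=25)
        assert ag.overlap_nodes == []

    def test_two_cycle_set_shares_hub(self):
        frags = figure_eight_set(seed=7)
        ag = build_graph(frags, limit=25)
        import networkx as nx
        sub = ag.graph.subgraph(ag.overlap_nodes)
        # per orientation: the designed pair of node-sharing cycles
        cycles = [set(c) for c in nx.simple_cycles(sub)]
        assert len(cycles) == 4  # two designed cycles x two faces
        shared = [c1 & c2 for c1, c2 in itertools.combinations(cycles, 2)
                  if c1 & c2]
        assert shared  # the hub node is shared


def brute_force_products(fragments, limit):
    """Try every fragment order/orientation and every exact shared region.

    Independent oracle for assemble(): returns (linear, circular) sets of
    canonical forms.  Joins follow single-strand-annealing semantics: a
    shared region merges the upstream fragment's prefix with the
    downstream fragment's suffix, and within one fragment the incoming
    junction must precede the outgoing one.
    """
    n = len(fragments)
    seqs = {}
    for i, f in enumerate(fragments):
        seqs[(i, 1)] = f.fill()
        seqs[(i, -1)] = reverse_complement(f.fill())
    pair = {}
    for ka in seqs:
        for kb in seqs:
            if ka[0] != kb[0]:
                pair[(ka, kb)] = dp_matches(seqs[ka], seqs[kb], limit)

    def canon_lin(s):
        return min(s, reverse_complement(s))

    def canon_circ(s):
        from clonesim.duplex import least_rotation
        return min(least_rotation(s), least_rotation(reverse_complement(s)))

    linear, circular = set(), set()
    for i in range(n):
        if any(pair[((i, 1), kb)] for kb in seqs if kb[0] != i):
            linear.add(canon_lin(seqs[(i, 1)]))

    keys = list(seqs)
    for k in range(2, n + 1):
        for combo in itertools.permutations(range(n), k):
            for orients in itertools.product((1, -1), repeat=k):
                okeys = [(combo[x], orients[x]) for x in range(k)]
                joins = [pair[(okeys[x], okeys[x + 1])] for x in range(k - 1)]
                for choice in itertools.product(*joins):
                    # linear chain: in-junction precedes out-junction
                    ok = all(choice[x][1] + choice[x - 1][2] <= choice[x][0]
                             for x in range(1, k - 1)) if k > 2 else True
                    # NB choice[x] = (q in okeys[x], p in okeys[x+1], l)
                    valid = True
                    for x in range(1, k - 1):
                        p_in = choice[x - 1][1]
                        l_in = choice[x - 1][2]
                        q_out = choice[x][0]
                        if p_in + l_in > q_out:
                            valid = False
                    if valid:
                        parts = [seqs[okeys[0]][:choice[0][0]]]
                        for x in range(k - 1):
                            q, p, ln = choice[x]
                            s_next = seqs[okeys[x + 1]]
                            stop = choice[x + 1][0] if x + 1 < k - 1 \
                                else len(s_next)
                            parts.append(s_next[p:p + ln])
                            parts.append(s_next[p + ln:stop])
                        linear.add(canon_lin("".join(parts)))
                    # circular closure: an extra join from last to first
                    for closing in pair[(okeys[-1], okeys[0])]:
                        qc, pc, lc = closing
                        cvalid = True
                        for x in range(k):
                            p_in, l_in = (choice[x - 1][1], choice[x - 1][2]) \
                                if x > 0 else (pc, lc)
                            q_out = choice[x][0] if x < k - 1 else qc
                            if p_in + l_in > q_out:
                                cvalid = False
                        if not cvalid:
                            continue
                        parts = []
                        allj = list(choice) + [closing]
                        for x in range(k):
                            q, p, ln = allj[x - 1] if x > 0 else closing
                            stop = allj[x][0]
                            s_cur = seqs[okeys[x]]
                            parts.append(s_cur[p:p + ln])
                            parts.append(s_cur[p + ln:stop])
                        circular.add(canon_circ("".join(parts)))
    return linear, circular


class TestAssemble:
    def test_three_fragment_circle(self):
        frags = overlapping_fragments(3, (150, 300), 30,
                                      circular_closure=True, seed=2)
        res = assemble(frags, limit=25)
        assert len(res.circular_products) == 1
        c = res.circular_products[0]
        assert c.span == sum(f.span for f in frags) - 3 * 30

    def test_two_cycle_semantics(self):
        frags = figure_eight_set(seed=1)
        res = assemble(frags, limit=25)
        assert len(res.circular_products) == 3
        largest = res.circular_products[0]
        assert {p[0] for p in largest.path} == {f.id for f in frags}
        subs = sorted(c.span for c in res.circular_products)[:2]
        # one hub junction is consumed per sub-circle turn, so the
        # combined product's span is exactly the sum of the two turns
        assert largest.span == sum(subs)

    def test_no_homology_no_multifragment_products(self, rng):
        a = AnnotatedMolecule.from_string(make_dna(rng, 200), id="a")
        b = AnnotatedMolecule.from_string(make_dna(rng, 200), id="b")
        res = assemble([a, b])
        assert res.linear_products == [] and res.circular_products == []

    def test_default_report_mentions_limit_25(self, rng):
        a = AnnotatedMolecule.from_string(make_dna(rng, 200), id="a")
        res = assemble([a])
        assert "limit 25" in res.report()

    def test_circular_input_rejected(self, circular_molecule):
        with pytest.raises(TopologyError):
            assemble([circular_molecule])

    @pytest.mark.parametrize("n,closure", [(2, True), (3, True), (3, False),
                                           (4, True), (4, False)])
    def test_products_equal_brute_force_oracle(self, n, closure):
        frags = overlapping_fragments(n, (60, 120), 20,
                                      circular_closure=closure,
                                      seed=100 + n + closure, limit=15)
        res = assemble(frags, limit=15)
        want_lin, want_circ = brute_force_products(frags, 15)
        got_lin = {c.molecule.canonical_form() for c in res.linear_products}
        got_circ = {c.molecule.canonical_form()
                    for c in res.circular_products}
        assert got_circ == want_circ
        assert got_lin == want_lin

    def test_figure_eight_matches_oracle(self):
        frags = figure_eight_set(seed=4)
        res = assemble(frags, limit=25)
        want_lin, want_circ = brute_force_products(frags, 25)
        assert {c.molecule.canonical_form()
                for c in res.circular_products} == want_circ

    def test_span_conservation(self):
        frags = overlapping_fragments(4, (100, 200), 25,
                                      circular_closure=True, seed=9)
        spans = {f.id: f.span for f in frags}
        res = assemble(frags, limit=20)
        for c in res.circular_products:
            total = sum(spans[fid] for fid, _, _ in c.path) \
                - sum(ol for _, _, ol in c.path)
            assert c.span == total

    def test_reverse_complement_symmetry(self):
        frags = overlapping_fragments(3, (100, 180), 25,
                                      circular_closure=True, seed=5)
        res_f = assemble(frags, limit=20)
        res_r = assemble([f.reverse_complement() for f in frags], limit=20)
        forward = {c.molecule.canonical_form() for c in res_f.circular_products}
        flipped = {c.molecule.canonical_form() for c in res_r.circular_products}
        assert forward == flipped

    def test_monotone_in_limit(self):
        frags = overlapping_fragments(3, (100, 180), 30,
                                      circular_closure=True, seed=6)
        low = assemble(frags, limit=20)
        high = assemble(frags, limit=31)
        low_set = {c.molecule.canonical_form() for c in low.circular_products}
        high_set = {c.molecule.canonical_form() for c in high.circular_products}
        assert high_set <= low_set
        assert high.circular_products == []  # 30 nt joins < limit 31


class TestContigFigure:
    def test_each_fragment_once_and_overlap_digits(self):
        frags = overlapping_fragments(3, (150, 300), 35,
                                      circular_closure=True, seed=8)
        res = assemble(frags, limit=25)
        fig = res.circular_products[0].figure()
        for f in frags:
            assert fig.count(f.id) >= 1
        printed = [int(x) for x in re.findall(r"\|(\d+)", fig)]
        assert printed == [ol for _, _, ol in res.circular_products[0].path]

    def test_single_fragment_contig_line(self, rng):
        from clonesim.assembly import Contig
        m = AnnotatedMolecule.from_string(make_dna(rng, 90), id="solo")
        c = Contig([("solo", 1, None)], False, m, {"solo": 90})
        assert c.figure() == "solo  -90"
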