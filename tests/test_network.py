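import hashlib
import random

import pytest

from mirhub.ingest import DbName, Direction, MirnaExpression
from mirhub.network import (
    HubMode,
    build_network,
    excluded_mirnas,
    export_edge_list,
    export_graphml,
    import_graphml,
    select_hubs,
    venn_partition,
)
from mirhub.scoring import EvidenceSet, ScoringConfig, retain_interactions

CFG = ScoringConfig()


def scored_edge(mirna, gene, dbs=(DbName.MIRDB, DbName.MICRORNA_ORG)):
    (si,) = retain_interactions([EvidenceSet(mirna, gene, frozenset(dbs))], CFG)
    return si


def expr(mirna, direction):
    return MirnaExpression(mirna, direction)


def make_random_network(seed, n_up=8, n_down=4, n_genes=15, n_edges=40):
    rng = random.Random(seed)
    ups = [f"rno-mir-u{i}" for i in range(n_up)]
    downs = [f"rno-mir-d{i}" for i in range(n_down)]
    expressions = [expr(m, Direction.UP) for m in ups] + [
        expr(m, Direction.DOWN) for m in downs
    ]
    pairs = set()
    while len(pairs) < n_edges:
        pairs.add((rng.choice(ups + downs), f"G{rng.randrange(n_genes)}"))
    scored = [scored_edge(m, g) for m, g in sorted(pairs)]
    return build_network(scored, expressions), expressions


# --- construction -------------------------------------------------------------


def test_build_small_network():
    expressions = [expr("rno-mir-1", Direction.UP), expr("rno-mir-2", Direction.UP)]
    scored = [scored_edge("rno-mir-1", "A"), scored_edge("rno-mir-2", "A")]
    net = build_network(scored, expressions)
    assert len(net.mirna_nodes) + len(net.gene_nodes) == 3
    assert net.n_edges == 2


def test_non_retained_interactions_are_ignored():
    expressions = [expr("rno-mir-1", Direction.UP)]
    not_retained = scored_edge("rno-mir-1", "A", dbs=(DbName.MIRDB,))
    assert not not_retained.retained
    net = build_network([not_retained], expressions)
    assert net.n_edges == 0
    assert "rno-mir-1" not in net.mirna_nodes


def test_edges_of_non_differential_mirnas_are_dropped():
    expressions = [expr("rno-mir-1", Direction.UP)]
    scored = [scored_edge("rno-mir-1", "A"), scored_edge("rno-mir-99", "B")]
    net = build_network(scored, expressions)
    assert net.n_edges == 1
    assert net.dropped_edges == 1


def test_empty_retained_set_gives_empty_network():
    net = build_network([], [expr("rno-mir-1", Direction.UP)])
    assert net.n_edges == 0 and not net.gene_nodes


def test_every_mirna_node_has_degree_at_least_one():
    net, _ = make_random_network(3)
    for m in net.mirna_nodes:
        assert any(edge[0] == m for edge in net.edges)


# --- excluded miRNAs -----------------------------------------------------------


def test_excluded_mirnas_partition():
    expressions = [
        expr("rno-mir-1", Direction.UP),
        expr("rno-mir-2", Direction.UP),
        expr("rno-mir-3", Direction.DOWN),
    ]
    # mir-2's only evidence is one predicted database: not retained
    scored = [
        scored_edge("rno-mir-1", "A"),
        scored_edge("rno-mir-2", "B", dbs=(DbName.MIRDB,)),
        scored_edge("rno-mir-3", "A"),
    ]
    net = build_network(scored, expressions)
    up, down = excluded_mirnas(expressions, net)
    assert (up, down) == (["rno-mir-2"], [])
    assert not set(up) & set(net.mirna_nodes)


def test_excluded_mirnas_trivial_cases():
    net, expressions = make_random_network(1)
    connected = [e for e in expressions if e.mirna_id in net.mirna_nodes]
    assert excluded_mirnas(connected, net) == ([], [])
    assert excluded_mirnas([], net) == ([], [])


# --- Venn partition -------------------------------------------------------------


def test_venn_example():
    expressions = [expr("rno-mir-u", Direction.UP), expr("rno-mir-d", Direction.DOWN)]
    scored = [
        scored_edge("rno-mir-u", "A"),
        scored_edge("rno-mir-d", "B"),
        scored_edge("rno-mir-u", "C"),
        scored_edge("rno-mir-d", "C"),
    ]
    venn = venn_partition(build_network(scored, expressions))
    assert (venn.up_only, venn.down_only, venn.both) == (1, 1, 1)
    assert venn.union_total == 3
    assert venn.naive_sum == 4  # shared gene counted twice


def test_venn_single_direction():
    expressions = [expr("rno-mir-u", Direction.UP)]
    venn = venn_partition(
        build_network([scored_edge("rno-mir-u", "A")], expressions)
    )
    assert venn.both == 0 and venn.up_only == 1


@pytest.mark.parametrize("seed", range(5))
def test_venn_matches_brute_force(seed):
    net, _ = make_random_network(seed)
    up_only = down_only = both = 0
    for g in net.gene_nodes:  # exhaustive per-gene classification
        dirs = {net.mirna_nodes[m].value for (m, gg) in net.edges if gg == g}
        if dirs == {"up"}:
            up_only += 1
        elif dirs == {"down"}:
            down_only += 1
        else:
            both += 1
    venn = venn_partition(net)
    assert (venn.up_only, venn.down_only, venn.both) == (up_only, down_only, both)
    assert venn.union_total == len(net.gene_nodes)


# --- hub selection ---------------------------------------------------------------


def ladder_network():
    """One gene at each total degree 1..6; gene G5 mixes up and down."""
    ups = [expr(f"rno-mir-u{i}", Direction.UP) for i in range(6)]
    downs = [expr(f"rno-mir-d{i}", Direction.DOWN) for i in range(2)]
    scored = []
    for deg in range(1, 7):
        gene = f"G{deg}"
        n_down = 2 if deg == 5 else 0
        for i in range(deg - n_down):
            scored.append(scored_edge(f"rno-mir-u{i}", gene))
        for i in range(n_down):
            scored.append(scored_edge(f"rno-mir-d{i}", gene))
    return build_network(scored, ups + downs)


def test_hub_threshold_on_total_degree():
    table = select_hubs(ladder_network(), CFG, HubMode.TOTAL)
    by_gene = table.set_index("gene_id")
    assert bool(by_gene.loc["G4", "is_hub"]) is True
    assert bool(by_gene.loc["G3", "is_hub"]) is False
    assert by_gene.loc["G5", "degree_total"] == 5
    assert (
        by_gene["degree_total"] == by_gene["degree_up"] + by_gene["degree_down"]
    ).all()


def test_hub_modes_differ_for_mixed_direction_gene():
    net = ladder_network()
    total = select_hubs(net, CFG, HubMode.TOTAL).set_index("gene_id")
    up_only = select_hubs(net, CFG, HubMode.UP_ONLY).set_index("gene_id")
    # G5 has degree_up=3, degree_down=2: hub in TOTAL mode only
    assert bool(total.loc["G5", "is_hub"]) is True
    assert bool(up_only.loc["G5", "is_hub"]) is False


def test_min_degree_one_makes_every_gene_a_hub():
    table = select_hubs(ladder_network(), ScoringConfig(hub_min_degree=1))
    assert table["is_hub"].all()


def test_hub_set_monotone_in_threshold():
    net, _ = make_random_network(11)
    hubs_at = {}
    for k in range(1, 7):
        t = select_hubs(net, ScoringConfig(hub_min_degree=k))
        hubs_at[k] = set(t.loc[t["is_hub"], "gene_id"])
    for k in range(1, 6):
        assert hubs_at[k + 1] <= hubs_at[k]


def test_up_only_hubs_subset_of_total():
    net, _ = make_random_network(12)
    total = select_hubs(net, CFG, HubMode.TOTAL)
    up = select_hubs(net, CFG, HubMode.UP_ONLY)
    assert set(up.loc[up["is_hub"], "gene_id"]) <= set(
        total.loc[total["is_hub"], "gene_id"]
    )


def test_hub_table_sort_order():
    table = select_hubs(ladder_network(), CFG)
    degrees = table["degree_total"].tolist()
    assert degrees == sorted(degrees, reverse=True)
    for _, group in table.groupby("degree_total"):
        genes = group["gene_id"].tolist()
        assert genes == sorted(genes)


# --- exports ----------------------------------------------------------------------


def test_graphml_round_trip(tmp_path):
    net, _ = make_random_network(21)
    path = tmp_path / "net.graphml"
    export_graphml(net, path)
    back = import_graphml(path)
    assert back.mirna_nodes == net.mirna_nodes
    assert back.gene_nodes == net.gene_nodes
    assert back.edges == net.edges


def test_graphml_small_and_empty(tmp_path):
    expressions = [expr("rno-mir-1", Direction.UP), expr("rno-mir-2", Direction.UP)]
    scored = [scored_edge("rno-mir-1", "A"), scored_edge("rno-mir-2", "A")]
    net = build_network(scored, expressions)
    p = tmp_path / "small.graphml"
    export_graphml(net, p)
    text = p.read_text()
    assert text.count("<node ") == 3 and text.count("<edge ") == 2

    empty = build_network([], expressions)
    q = tmp_path / "empty.graphml"
    export_graphml(empty, q)
    assert import_graphml(q).n_edges == 0


def test_edge_list_deterministic_and_round_trips(tmp_path):
    net, _ = make_random_network(33)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    export_edge_list(net, p1)
    export_edge_list(net, p2)
    assert hashlib.sha256(p1.read_bytes()).hexdigest() == hashlib.sha256(
        p2.read_bytes()
    ).hexdigest()
    lines = p1.read_text().splitlines()
    assert len(lines) == net.n_edges + 1
    edges = {(l.split("\t")[0], l.split("\t")[2]) for l in lines[1:]}
    assert edges == set(net.edges)
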