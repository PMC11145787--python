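import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from hmcnet.genome_io import CoverageTrack, GeneModel, GeneSet
from hmcnet.ghmcn import (
    GenomeGraph,
    GhmcnClassifier,
    GhmcnConfig,
    build_genome_graph,
    nearest1d_graph,
)
from hmcnet.hic import ContactMap


def toy_graph(n=200, seed=0, label_from="self", edges=None, fold_seed=0):
    """A small graph whose labels derive from the node's own IP feature."""
    rng = np.random.default_rng(seed)
    ip = rng.normal(0, 1, n)
    inp = rng.normal(0, 1, n)
    labels = np.full(n, np.nan)
    mask = np.ones(n, dtype=bool)
    if label_from == "self":
        labels[:] = (ip > 0).astype(float)
    nodes = pd.DataFrame(
        {"chrom": "chr1", "bin": np.arange(n), "ip": ip, "input": inp,
         "label": labels, "mask": mask}
    )
    frng = np.random.default_rng(fold_seed)
    folds = np.array([""] * n, dtype=object)
    order = frng.permutation(n)
    folds[order[: int(0.7 * n)]] = "train"
    folds[order[int(0.7 * n) : int(0.85 * n)]] = "val"
    folds[order[int(0.85 * n) :]] = "test"
    nodes["fold"] = folds
    if edges is None:
        edges = np.array([[i, i + 1] for i in range(n - 1)], dtype=np.int64)
    return GenomeGraph(nodes=nodes, edges=edges)


class TestGraphConstruction:
    @staticmethod
    def tiny_setup():
        bs = 10_000
        n_bins = 6
        genes = GeneSet(
            [
                GeneModel("a", "chr1", 1_000, 4_000, "+"),  # TSS bin 0
                GeneModel("b", "chr1", 8_000, 12_000, "+"),  # TSS bin 0 too
                GeneModel("c", "chr1", 25_000, 29_000, "+"),  # TSS bin 2
                GeneModel("d", "chr1", 45_000, 49_000, "+"),  # TSS bin 4
            ]
        )
        tpm = pd.Series({"a": 2.0, "b": 4.0, "c": 10.0, "d": 0.1})
        D = np.zeros((n_bins, n_bins))
        for i in range(n_bins - 1):
            D[i, i + 1] = D[i + 1, i] = 5.0
        cmap = ContactMap("chr1", sp.csr_matrix(D), bin_size=bs, distance_normalized=True)
        track = CoverageTrack({"chr1": ([0], [n_bins * bs], [1.0])}, total_mapped=1e6)
        return genes, tpm, {"chr1": cmap}, track

    def test_multi_tss_node_takes_mean_tpm(self):
        genes, tpm, maps, track = self.tiny_setup()
        g = build_genome_graph(maps, track, track, genes, tpm, k=2, seed=0)
        # bin 0 holds TSSs of a (2.0) and b (4.0): mean 3.0 = median -> Low (strict >)
        assert g.nodes.loc[0, "mask"]
        assert g.nodes.loc[0, "label"] == 0.0
        assert g.nodes.loc[2, "label"] == 1.0  # 10.0 > median 3.0
        assert g.nodes.loc[4, "label"] == 0.0

    def test_nodes_without_tss_unlabeled(self):
        genes, tpm, maps, track = self.tiny_setup()
        g = build_genome_graph(maps, track, track, genes, tpm, k=2, seed=0)
        assert not g.nodes.loc[1, "mask"]
        assert np.isnan(g.nodes.loc[1, "label"])
        assert g.nodes.loc[1, "fold"] == ""

    def test_fold_fractions_70_15_15(self):
        g = toy_graph(n=100)
        counts = g.nodes["fold"].value_counts()
        assert counts["train"] == 70 and counts["val"] == 15 and counts["test"] == 15

    def test_labels_only_on_masked_nodes_enforced(self):
        nodes = pd.DataFrame(
            {"chrom": ["chr1"], "bin": [0], "ip": [0.0], "input": [0.0],
             "label": [1.0], "mask": [False], "fold": [""]}
        )
        with pytest.raises(ValueError):
            GenomeGraph(nodes=nodes, edges=np.empty((0, 2), dtype=np.int64))


class TestNearest1d:
    def test_interior_bin_degree_10(self):
        edges = nearest1d_graph({"chr1": 30}, k=10)
        deg = np.zeros(30, int)
        for a, b in edges:
            deg[a] += 1
            deg[b] += 1
        assert deg[15] == 10

    def test_first_bin_degree_5(self):
        edges = nearest1d_graph({"chr1": 30}, k=10)
        deg0 = sum(1 for e in edges if 0 in e)
        assert deg0 == 5

    def test_independent_of_contacts(self):
        a = nearest1d_graph({"chr1": 20}, k=10)
        b = nearest1d_graph({"chr1": 20}, k=10)
        assert np.array_equal(a, b)


class TestTraining:
    def test_self_feature_labels_learned(self):
        """Labels thresholded on the node's own IP are recovered with high AUC."""
        g = toy_graph(n=400, seed=1)
        res = GhmcnClassifier(g, GhmcnConfig(seed=0, epochs=400)).fit()
        assert res.report.auc >= 0.95

    def test_label_shuffle_gives_chance_auc(self):
        g = toy_graph(n=400, seed=1)
        rng = np.random.default_rng(5)
        nodes = g.nodes.copy()
        nodes["label"] = rng.permutation(nodes["label"].to_numpy())
        g2 = GenomeGraph(nodes=nodes, edges=g.edges)
        res = GhmcnClassifier(g2, GhmcnConfig(seed=0, epochs=400)).fit()
        assert res.report.auc == pytest.approx(0.5, abs=0.12)

    def test_single_class_training_rejected(self):
        g = toy_graph(n=50)
        nodes = g.nodes.copy()
        nodes["label"] = 1.0
        with pytest.raises(ValueError):
            GhmcnClassifier(GenomeGraph(nodes=nodes, edges=g.edges)).fit()

    def test_loop_graph_beats_1d_graph_on_loop_labels(self, loop_study, ghmcn_results):
        """With labels carried by a distal loop partner, the Hi-C wiring wins
        over the 1D-nearest control."""
        graph = loop_study["graph"]
        edges_1d = nearest1d_graph(
            {c: m.n_bins for c, m in loop_study["normed"].items()}, k=10
        )
        res_1d = GhmcnClassifier(graph.with_edges(edges_1d), GhmcnConfig(seed=7)).fit()
        assert ghmcn_results.report.auc > res_1d.report.auc

    def test_cell_specific_map_beats_aggregate_on_loop_labels(self, loop_study):
        """Aggregating the loop-bearing map with loop-free maps from other
        'cell types' dilutes the label-carrying edges, so the cell-specific
        graph scores at least as well as the aggregate graph."""
        from hmcnet.hic import aggregate_maps, distance_normalize, map_to_pairs
        from hmcnet.synthetic import SyntheticGenome, synth_hic
        import pandas as pd

        genome = loop_study["genome"]
        graph = loop_study["graph"]
        # two partner datasets from the same genome but without any loops
        loopless = SyntheticGenome(
            genes=genome.genes,
            expression=genome.expression,
            planted_labels=genome.planted_labels,
            enhancers=genome.enhancers.iloc[0:0],
            config=genome.config,
        )
        n_bins = {c: m.n_bins for c, m in loop_study["maps"].items()}
        pairs_by_ds = {"specific": pd.concat(
            [p.frame for p in loop_study["pairs"].values()]
        )}
        for name, seed in (("other1", 31), ("other2", 32)):
            maps, pl = synth_hic(loopless, seed=seed)
            pairs_by_ds[name] = pd.concat([p.frame for p in pl.values()])
        from hmcnet.hic import PairList

        pls = {k: PairList(v.reset_index(drop=True)) for k, v in pairs_by_ds.items()}
        n_each = min(pl.total for pl in pls.values())
        agg = aggregate_maps(pls, n_each=n_each, n_bins=n_bins, seed=0)
        agg_normed = {c: distance_normalize(m) for c, m in agg.items()}
        from hmcnet.hic import topk_graph
        from hmcnet.ghmcn import _chrom_offsets

        offsets = _chrom_offsets(n_bins)
        agg_edges = []
        for chrom, m in agg_normed.items():
            e = topk_graph(m, k=10)
            if len(e):
                agg_edges.append(e + offsets[chrom])
        agg_graph = graph.with_edges(np.vstack(agg_edges))

        cfg = GhmcnConfig(seed=7, epochs=600)
        auc_specific = GhmcnClassifier(graph, cfg).fit().report.auc
        auc_aggregate = GhmcnClassifier(agg_graph, cfg).fit().report.auc
        assert auc_specific >= auc_aggregate

    def test_training_is_deterministic_per_seed(self):
        g = toy_graph(n=100)
        a = GhmcnClassifier(g, GhmcnConfig(seed=3, epochs=50)).fit()
        b = GhmcnClassifier(g, GhmcnConfig(seed=3, epochs=50)).fit()
        assert np.allclose(a.history, b.history)
        assert a.report.auc == b.report.auc


class TestPrediction:
    def test_scores_in_unit_interval(self, ghmcn_results):
        # sigmoid outputs; confident logits round to the boundary in float64
        p = ghmcn_results.predict()
        assert np.isfinite(p).all()
        assert ((p >= 0) & (p <= 1)).all()

    def test_reapplying_to_training_graph_reproduces_scores(self, ghmcn_results):
        a = ghmcn_results.predict()
        b = ghmcn_results.predict(ghmcn_results.graph)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_feature_arity_mismatch_rejected(self, ghmcn_results):
        class ThreeFeatureGraph(GenomeGraph):
            @property
            def features(self):
                base = super().features
                return np.hstack([base, np.zeros((len(base), 1))])

        g = ghmcn_results.graph
        bad = ThreeFeatureGraph(nodes=g.nodes, edges=g.edges)
        with pytest.raises(ValueError):
            ghmcn_results.predict(bad)

    def test_receptive_field_limited_to_conv_depth(self):
        """Perturbing nodes beyond conv-depth hops leaves a node's score unchanged."""
        n = 60
        g = toy_graph(n=n, seed=2)
        res = GhmcnClassifier(g, GhmcnConfig(seed=0, epochs=30)).fit()
        target = 30
        base = res.predict().loc[target]
        nodes = g.nodes.copy()
        far = np.abs(np.arange(n) - target) > res.config.conv_layers
        nodes.loc[far, "ip"] = nodes.loc[far, "ip"] + 100.0  # big perturbation far away
        pert = GenomeGraph(nodes=nodes, edges=g.edges)
        assert res.predict(pert).loc[target] == pytest.approx(base, abs=1e-12)


class TestSerialization:
    def test_graph_tsv_roundtrip(self, tmp_path, loop_study):
        g = loop_study["graph"]
        g.to_tsv(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        back = GenomeGraph.from_tsv(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
        assert back.n_nodes == g.n_nodes
        assert np.array_equal(back.edges, g.edges)
        assert np.allclose(back.features, g.features)
        assert (back.nodes["fold"] == g.nodes["fold"]).all()
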