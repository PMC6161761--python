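import numpy as np
import pytest

from cnepairs.io import GenomicInterval, read_bed
from cnepairs.pairs import rbh_orthologs
from cnepairs.simulate import (SPECIES, SimConfig, default_tree_newick,
                               emit_elements_and_pairs, emit_tracks,
                               emit_transposons, simulate_all,
                               simulate_distances)
from cnepairs.io import parse_newick_string
from cnepairs.transposons import TransposonAnnotation, transposon_density


class TestDefaultTree:
    def test_23_species_ultrametric(self):
        tree = parse_newick_string(default_tree_newick())
        depths = {}
        for n in tree.preorder_node_iter():
            depths[n] = depths.get(n.parent_node, 0.0) + (n.edge.length or 0.0)
        tip_depths = [depths[l] for l in tree.leaf_node_iter()]
        assert len(tip_depths) == len(SPECIES) == 23
        assert np.allclose(tip_depths, 430.0)


class TestSimulateDistances:
    def test_zero_noise_limit_tips_equal_ancestor(self):
        cfg = SimConfig(seed=3, n_pairs=20, sigma2=1e-12,
                        class_fractions={"contracted": 0, "conserved": 1.0,
                                         "expanded": 0})
        dist, truth = simulate_distances(cfg)
        for pid, t in truth.pairs.items():
            expected = np.rint(t.d_r)
            assert np.all(dist.loc[pid].to_numpy() == expected)

    def test_class_shift_forced_on_focal_tip(self):
        cfg = SimConfig(seed=3, n_pairs=30, sigma2=1e-12)
        dist, truth = simulate_distances(cfg)
        for pid, t in truth.pairs.items():
            d_r = np.rint(t.d_r)
            if t.cls == "contracted":
                assert dist.loc[pid, "human"] == max(np.rint(0.5 * t.d_r), 200)
            elif t.cls == "expanded":
                assert dist.loc[pid, "human"] == np.rint(2.0 * t.d_r)
            else:
                assert dist.loc[pid, "human"] == d_r
            assert dist.loc[pid, "platypus"] == d_r

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(seed=9, n_pairs=15)
        d1, t1 = simulate_distances(cfg)
        d2, t2 = simulate_distances(cfg)
        assert d1.equals(d2)
        assert {k: v.archetype for k, v in t1.pairs.items()} \
            == {k: v.archetype for k, v in t2.pairs.items()}

    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(class_fractions={"contracted": 0.5, "conserved": 0.1,
                                       "expanded": 0.1})


class TestEmitElements:
    def test_midpoint_distances_match_simulation_exactly(self):
        cfg = SimConfig(seed=5, n_pairs=25)
        dist, truth = simulate_distances(cfg)
        layouts, _f, _r = emit_elements_and_pairs(cfg, dist, truth)
        for sp in ("human", "platypus", "zebrafish"):
            layout = layouts[sp]
            for pid in dist.index:
                left, right = layout.pair_region[pid]
                assert right.midpoint - left.midpoint == dist.loc[pid, sp]
                # the inter-CNE gap survives the <100bp merge rule
                assert right.start - left.end >= 100

    def test_rbh_recovers_all_orthologs_without_decoys(self):
        cfg = SimConfig(seed=5, n_pairs=15, decoy_fraction=0.0)
        dist, truth = simulate_distances(cfg)
        layouts, fwd, rev = emit_elements_and_pairs(cfg, dist, truth)
        queries = {f"{iv.chrom}:{iv.start}-{iv.end}": iv
                   for iv, _n in layouts["human"].elements}
        omap = rbh_orthologs(fwd, rev, queries)
        n_species = len(cfg.species) - 1
        assert len(omap) == len(queries)
        assert all(len(v) == n_species for v in omap.values())

    def test_rbh_violations_are_rejected(self):
        cfg = SimConfig(seed=5, n_pairs=40, rbh_violation_fraction=1.0)
        dist, truth = simulate_distances(cfg)
        layouts, fwd, rev = emit_elements_and_pairs(cfg, dist, truth)
        queries = {f"{iv.chrom}:{iv.start}-{iv.end}": iv
                   for iv, _n in layouts["human"].elements}
        assert rbh_orthologs(fwd, rev, queries) == {}


class TestEmitTransposons:
    def test_zero_densities_give_empty_planted_content(self):
        cfg = SimConfig(seed=6, n_pairs=10, transposon_free_fraction=1.0,
                        background_te_density={"SINE": 1e-9, "LINE": 1e-9,
                                               "LTR": 1e-9, "DNA": 1e-9})
        dist, truth = simulate_distances(cfg)
        layouts, _f, _r = emit_elements_and_pairs(cfg, dist, truth)
        recs = emit_transposons(cfg, truth, layouts)
        assert all(t.transposon_free for t in truth.pairs.values())
        # essentially no content anywhere at vanishing background density
        assert len(recs["human"]) < 5

    def test_transposon_free_pairs_have_zero_overlap_everywhere(self):
        cfg = SimConfig(seed=7, n_pairs=30)
        dist, truth = simulate_distances(cfg)
        layouts, _f, _r = emit_elements_and_pairs(cfg, dist, truth)
        recs = emit_transposons(cfg, truth, layouts)
        free = [pid for pid, t in truth.pairs.items() if t.transposon_free]
        assert free, "expected some transposon-free pairs at fraction 0.15"
        for sp in ("human", "platypus"):
            ann = TransposonAnnotation(recs[sp])
            for pid in free:
                left, right = layouts[sp].pair_region[pid]
                region = GenomicInterval(layouts[sp].chrom,
                                         left.midpoint, right.midpoint)
                assert transposon_density(region, ann).total_density == 0.0

    def test_background_coverage_near_expectation(self):
        """Binomial placement oracle: ~0.46 covered fraction on free genome."""
        cfg = SimConfig(seed=8, n_pairs=2)
        dist, truth = simulate_distances(cfg)
        layouts, _f, _r = emit_elements_and_pairs(cfg, dist, truth)
        # use a 1-Mb decoy chromosome away from the planted pairs
        layouts["human"].chrom_len = max(layouts["human"].chrom_len, 1_200_000)
        recs = emit_transposons(cfg, truth, layouts)
        ann = TransposonAnnotation(recs["human"])
        decoy = GenomicInterval("chr1", layouts["human"].chrom_len - 1_000_000,
                                layouts["human"].chrom_len)
        frac = transposon_density(decoy, ann).total_density
        assert abs(frac - 0.46) < 0.03


class TestEmitTracks:
    def _tracks(self, noise=0.0, seed=4):
        cfg = SimConfig(seed=seed, n_pairs=20, n_tissues=1, noise_sd=noise)
        dist, truth = simulate_distances(cfg)
        layouts, _f, _r = emit_elements_and_pairs(cfg, dist, truth)
        return cfg, truth, layouts["human"], emit_tracks(cfg, truth, layouts["human"])

    def test_inactive_pair_at_baseline_without_noise(self):
        cfg, truth, layout, tracks = self._tracks(noise=0.0)
        inactive = [pid for pid, t in truth.pairs.items()
                    if t.archetype == "inactive"]
        assert inactive
        left, right = layout.pair_region[inactive[0]]
        for (tissue, mark), track in tracks.items():
            for iv in (GenomicInterval(layout.chrom, left.midpoint - 150,
                                       left.midpoint + 150),
                       GenomicInterval(layout.chrom, left.end, right.start)):
                assert track.mean_over(iv) == pytest.approx(1.0)

    def test_active_pair_cne_window_at_amplitude(self):
        cfg, truth, layout, tracks = self._tracks(noise=0.0)
        active = [pid for pid, t in truth.pairs.items()
                  if t.archetype == "CNE_active"]
        assert active
        left, _right = layout.pair_region[active[0]]
        window = GenomicInterval(layout.chrom, left.midpoint - 150,
                                 left.midpoint + 150)
        assert tracks[("tissue01", "H3K27ac")].mean_over(window) \
            == pytest.approx(1.0 + cfg.signal_amplitude)

    def test_fixed_seed_identical_tracks(self):
        _c1, _t1, _l1, tr1 = self._tracks(noise=0.3, seed=11)
        _c2, _t2, _l2, tr2 = self._tracks(noise=0.3, seed=11)
        key = ("tissue01", "H3K4me1")
        assert tr1[key].bins() == tr2[key].bins()


class TestSimulateAll:
    def test_directory_tree_and_byte_identity(self, tmp_path):
        cfg = SimConfig(seed=13, n_pairs=8, n_tissues=1)
        t1 = simulate_all(cfg, tmp_path / "a")
        t2 = simulate_all(cfg, tmp_path / "b")
        for rel in ("elements/human.bed", "transposons/platypus.bed",
                    "tracks/tissue01_H3K27ac.bedGraph", "tree.nwk",
                    "hits_forward.tsv", "truth.json", "genome.tsv",
                    "annotation.gtf", "config.yaml"):
            fa, fb = tmp_path / "a" / rel, tmp_path / "b" / rel
            assert fa.exists()
            assert fa.read_bytes() == fb.read_bytes(), rel
        assert set(t1.pairs) == set(t2.pairs)
        # elements BED is valid and ordered
        recs = read_bed(tmp_path / "a" / "elements" / "human.bed")
        starts = [iv.start for iv, _n, _s in recs]
        assert starts == sorted(starts)
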