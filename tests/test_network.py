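"""Reaction-network construction: channel sets, RHS, Jacobian, conservation."""

import numpy as np
import pytest

from aggkin import (
    KineticParams,
    Reaction,
    ReactionKind,
    SizeDistribution,
    Variant,
    build_aggregation_network,
    build_clustering_network,
    build_network,
)
from aggkin.network import InvalidSizeError

from conftest import random_state

AGG = KineticParams(variant=Variant.AGGREGATION,
                    k1=0.3, k2=0.7, k_m1=0.11, k_m2=0.05, k3=0.02, p0=2.0)
CLU = KineticParams(variant=Variant.CLUSTERING,
                    k1=0.3, k2=0.7, k_m1=0.11, k_m2=0.05, p0=2.0)


def channel_set(network):
    return {(r.kind, r.i, r.j, r.rate_label) for r in network.reactions}


class TestChannelEnumeration:
    def test_aggregation_n1_has_no_channels(self):
        assert build_aggregation_network(1, AGG).reactions == []

    def test_aggregation_n2_exact(self):
        C, F = ReactionKind.COAGULATION, ReactionKind.FRAGMENTATION
        assert channel_set(build_aggregation_network(2, AGG)) == {
            (C, 1, 1, "k2"),
            (F, 1, 1, "k_m1"),
        }

    def test_aggregation_n4_exact(self):
        C, F = ReactionKind.COAGULATION, ReactionKind.FRAGMENTATION
        assert channel_set(build_aggregation_network(4, AGG)) == {
            (C, 1, 1, "k2"), (C, 1, 2, "k1"), (C, 1, 3, "k1"), (C, 2, 2, "k_m2"),
            (F, 1, 1, "k_m1"), (F, 1, 2, "k_m1"), (F, 1, 3, "k_m1"),
            (F, 2, 2, "k3"),
        }

    def test_clustering_n3_exact(self):
        C, F = ReactionKind.COAGULATION, ReactionKind.FRAGMENTATION
        # the (1,2) pair carries BOTH the monomer and the dimer channel
        assert channel_set(build_clustering_network(3, CLU)) == {
            (C, 1, 1, "k1"), (C, 1, 2, "k1"), (C, 1, 2, "k2"),
            (F, 1, 1, "k_m1"), (F, 1, 2, "k_m1"), (F, 1, 2, "k_m2"),
        }

    def test_clustering_n5_exact(self):
        C, F = ReactionKind.COAGULATION, ReactionKind.FRAGMENTATION
        assert channel_set(build_clustering_network(5, CLU)) == {
            (C, 1, 1, "k1"), (C, 1, 2, "k1"), (C, 1, 3, "k1"), (C, 1, 4, "k1"),
            (C, 1, 2, "k2"), (C, 2, 2, "k2"), (C, 2, 3, "k2"),
            (F, 1, 1, "k_m1"), (F, 1, 2, "k_m1"), (F, 1, 3, "k_m1"),
            (F, 1, 4, "k_m1"),
            (F, 1, 2, "k_m2"), (F, 2, 2, "k_m2"), (F, 2, 3, "k_m2"),
        }

    @pytest.mark.parametrize("N", range(1, 16))
    def test_aggregation_channel_counts_brute_force(self, N):
        # every unordered pair (i, j) with i + j <= N coagulates exactly once;
        # every size s splits into floor(s/2) channels
        net = build_aggregation_network(N, AGG)
        n_coag = sum(1 for r in net.reactions if r.kind is ReactionKind.COAGULATION)
        n_frag = sum(1 for r in net.reactions if r.kind is ReactionKind.FRAGMENTATION)
        assert n_coag == sum(
            1 for i in range(1, N + 1) for j in range(i, N + 1) if i + j <= N
        )
        assert n_frag == sum(s // 2 for s in range(2, N + 1))

    @pytest.mark.parametrize("N", range(1, 16))
    def test_clustering_channel_counts_brute_force(self, N):
        # one channel per (row, pair) with row in {monomer, dimer}; forward
        # and backward channel counts match (micro-reversibility of the scheme)
        net = build_clustering_network(N, CLU)
        n_coag = sum(1 for r in net.reactions if r.kind is ReactionKind.COAGULATION)
        n_frag = sum(1 for r in net.reactions if r.kind is ReactionKind.FRAGMENTATION)
        expect_mono = sum(1 for j in range(1, N + 1) if 1 + j <= N)
        expect_di = sum(1 for j in range(1, N + 1) if 2 + j <= N)
        assert n_coag == expect_mono + expect_di
        assert n_frag == n_coag

    def test_invalid_sizes_rejected(self):
        with pytest.raises(InvalidSizeError):
            build_aggregation_network(0, AGG)
        with pytest.raises(InvalidSizeError):
            Reaction(ReactionKind.COAGULATION, 2, 1, "k1")

    def test_variant_mismatch_rejected(self):
        from aggkin.params import VariantMismatchError

        with pytest.raises(VariantMismatchError):
            build_aggregation_network(4, CLU)
        with pytest.raises(VariantMismatchError):
            build_clustering_network(4, AGG)

    def test_two_equation_has_no_network(self):
        two = KineticParams(variant=Variant.TWO_EQUATION, k1=1.0)
        with pytest.raises(ValueError):
            build_network(4, two)


class TestRhs:
    def test_all_monomer_aggregation(self):
        # from [1] = p0 only the dimerization channel fires:
        # d[1] = -2*k2*p0**2, d[2] = +k2*p0**2
        net = build_aggregation_network(4, AGG)
        c = SizeDistribution.all_monomer(4, AGG.p0).c
        dc = net.rhs(c)
        rate = AGG.k2 * AGG.p0**2
        assert dc == pytest.approx([-2.0 * rate, rate, 0.0, 0.0])

    def test_all_monomer_clustering(self):
        net = build_clustering_network(4, CLU)
        c = SizeDistribution.all_monomer(4, CLU.p0).c
        dc = net.rhs(c)
        rate = CLU.k1 * CLU.p0**2
        assert dc == pytest.approx([-2.0 * rate, rate, 0.0, 0.0])

    def test_hand_worked_aggregation_n3(self):
        # c = (a, b, d):  channels (1,1)->2 @ k2*a^2, (1,2)->3 @ k1*a*b,
        # fissions 2->(1,1) @ km1*b, 3->(1,2) @ km1*d
        a, b, d = 0.9, 0.4, 0.2
        net = build_aggregation_network(3, AGG)
        k1, k2, km1 = AGG.k1, AGG.k2, AGG.k_m1
        expect = np.array([
            -2.0 * k2 * a * a - k1 * a * b + 2.0 * km1 * b + km1 * d,
            k2 * a * a - k1 * a * b - km1 * b + km1 * d,
            k1 * a * b - km1 * d,
        ])
        assert net.rhs(np.array([a, b, d])) == pytest.approx(expect, rel=1e-14)

    def test_hand_worked_clustering_n4(self):
        # channels: (1,1)@k1, (1,2)@k1, (1,2)@k2, (1,3)@k1, (2,2)@k2
        # fissions: 2->(1,1)@km1, 3->(1,2)@km1 and @km2, 4->(1,3)@km1, 4->(2,2)@km2
        a, b, d, e = 0.9, 0.4, 0.2, 0.1
        k1, k2, km1, km2 = CLU.k1, CLU.k2, CLU.k_m1, CLU.k_m2
        net = build_clustering_network(4, CLU)
        expect = np.array([
            (-2.0 * k1 * a * a - k1 * a * b - k2 * a * b - k1 * a * d
             + 2.0 * km1 * b + km1 * d + km2 * d + km1 * e),
            (k1 * a * a - k1 * a * b - k2 * a * b - 2.0 * k2 * b * b
             - km1 * b + km1 * d + km2 * d + 2.0 * km2 * e),
            (k1 * a * b + k2 * a * b - k1 * a * d - km1 * d - km2 * d + km1 * e),
            (k1 * a * d + k2 * b * b - km1 * e - km2 * e),
        ])
        assert net.rhs(np.array([a, b, d, e])) == pytest.approx(expect, rel=1e-14)

    def test_zero_rates_give_zero_rhs(self):
        frozen = KineticParams(variant=Variant.AGGREGATION, p0=1.0)
        net = build_aggregation_network(6, frozen)
        assert np.all(net.rhs(random_state(6, 1)) == 0.0)

    def test_wrong_dimension_rejected(self):
        net = build_aggregation_network(4, AGG)
        with pytest.raises(InvalidSizeError):
            net.rhs(np.ones(5))

    @pytest.mark.parametrize("builder,params", [
        (build_aggregation_network, AGG), (build_clustering_network, CLU),
    ])
    @pytest.mark.parametrize("N", [1, 2, 3, 5, 8, 13])
    def test_mass_conservation_pointwise(self, builder, params, N):
        # sum(i * d[i]/dt) = 0 identically: every channel conserves mass
        net = builder(N, params)
        sizes = np.arange(1, N + 1)
        for seed in range(5):
            c = random_state(N, seed)
            assert abs(sizes @ net.rhs(c)) < 1e-12 * (sizes @ c)


class TestJacobian:
    @pytest.mark.parametrize("builder,params", [
        (build_aggregation_network, AGG), (build_clustering_network, CLU),
    ])
    @pytest.mark.parametrize("N", [2, 4, 7, 10])
    def test_matches_finite_differences(self, builder, params, N):
        net = builder(N, params)
        c = random_state(N, N)
        J = net.jacobian(c)
        h = 1e-6
        for k in range(N):
            e = np.zeros(N)
            e[k] = h
            col = (net.rhs(c + e) - net.rhs(c - e)) / (2.0 * h)
            assert J[:, k] == pytest.approx(col, rel=1e-6, abs=1e-8)

    def test_mass_is_left_null_vector(self):
        # d/dc of sum(i*rhs_i) = 0, so sizes @ J = 0 for any state
        net = build_aggregation_network(8, AGG)
        c = random_state(8, 3)
        sizes = np.arange(1, 9, dtype=float)
        assert np.max(np.abs(sizes @ net.jacobian(c))) < 1e-12


class TestDump:
    def test_dump_round_trips_channels(self):
        net = build_clustering_network(4, CLU)
        dumped = net.dump()
        assert len(dumped) == len(net.reactions)
        assert dumped[0].keys() == {"kind", "sizes", "product_or_source", "rate_label"}
        for rec, r in zip(dumped, net.reactions):
            assert rec["sizes"] == [r.i, r.j]
            assert rec["product_or_source"] == r.i + r.j
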