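"""Motivation computation, GOS competition, hysteresis and dissipation."""

import dataclasses

import pytest

from ahasim import Architecture, CircuitSpec, ConfigurationError, GOSState
from ahasim.cognition import appraise, dissipate, hill, motivation, switching_threshold
from ahasim.genome import Genome, LinkParams
from ahasim.rng import child_rng


def make_genome(links, hyst=(0.0, 0.0), attention=0.0, diss_rate=0.0, onset=10):
    return Genome(link_params=links, attention_strength=attention,
                  hysteresis_lo=hyst[0], hysteresis_hi=hyst[1],
                  dissipation_rate=diss_rate, dissipation_onset=onset)


def single_modality_arch(n):
    """n circuits c0..c(n-1), each reading its own modality m0..m(n-1)."""
    return Architecture(circuits=tuple(
        CircuitSpec(f"c{i}", "negative", (f"m{i}",)) for i in range(n)))


def genome_for(arch, gain=1.0, half_sat=0.5, weight=1.0, **kw):
    links = {(c.circuit_id, m): LinkParams(gain, half_sat, weight)
             for c in arch.circuits for m in c.modalities}
    return make_genome(links, **kw)


def stimulus_for_motivation(m, half_sat=0.5):
    """Invert the gain-1 Hill function: x such that x/(x+h) = m."""
    return half_sat * m / (1.0 - m)


class TestMotivation:
    def test_zero_stimuli_zero_motivation(self):
        arch = single_modality_arch(1)
        g = genome_for(arch)
        assert motivation({"m0": 0.0}, arch.circuits[0], g) == 0.0

    def test_half_saturation_point(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, gain=1.0, half_sat=0.5)
        assert motivation({"m0": 0.5}, arch.circuits[0], g) == pytest.approx(0.5)

    def test_weighted_mean_of_two_modalities(self):
        # R values 0.8 and 0.4 with weights 0.75 / 0.25 -> 0.7
        circuit = CircuitSpec("c", "negative", ("m0", "m1"))
        links = {("c", "m0"): LinkParams(gain=1.0, half_sat=0.25, weight=0.75),
                 ("c", "m1"): LinkParams(gain=1.0, half_sat=0.6, weight=0.25)}
        g = make_genome(links)
        # m0 = 1.0: R = 1/(1+0.25) = 0.8 ; m1 = 0.4: R = 0.4/(0.4+0.6) = 0.4
        m = motivation({"m0": 1.0, "m1": 0.4}, circuit, g)
        assert m == pytest.approx(0.7)

    def test_all_weights_zero_rejected(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, weight=0.0)
        with pytest.raises(ConfigurationError):
            motivation({"m0": 0.5}, arch.circuits[0], g)

    def test_monotone_in_every_gated_stimulus(self):
        arch = single_modality_arch(1)
        rng = child_rng(1, "mono")
        for _ in range(200):
            g = genome_for(arch, gain=float(rng.uniform(0.2, 4)),
                           half_sat=float(rng.uniform(0.01, 1.0)))
            xs = sorted(rng.uniform(size=5))
            ms = [motivation({"m0": float(x)}, arch.circuits[0], g) for x in xs]
            assert all(b >= a - 1e-12 for a, b in zip(ms, ms[1:]))
            assert all(0.0 <= m <= 1.0 for m in ms)


class TestAppraise:
    def test_single_winner_among_three(self):
        arch = single_modality_arch(3)
        g = genome_for(arch)
        s = {f"m{i}": stimulus_for_motivation(m) for i, m in enumerate((0.6, 0.2, 0.1))}
        prev = GOSState("c2", arousal=0.0)
        M, gos = appraise(s, arch, prev, g)
        assert gos.dominant == "c0"
        assert M["c0"] == pytest.approx(0.6)
        assert gos.arousal == pytest.approx(0.6)

    def test_small_fluctuation_tolerated(self):
        """A 0.52 challenger does not displace a 0.50 incumbent at theta=0.05."""
        arch = single_modality_arch(2)
        g = genome_for(arch, hyst=(0.05, 0.05))
        s = {"m0": stimulus_for_motivation(0.50), "m1": stimulus_for_motivation(0.52)}
        prev = GOSState("c0", arousal=0.5, bout_length=4)
        _, gos = appraise(s, arch, prev, g)
        assert gos.dominant == "c0"
        assert gos.bout_length == 5

    def test_clear_challenger_switches(self):
        arch = single_modality_arch(2)
        g = genome_for(arch, hyst=(0.05, 0.05))
        s = {"m0": stimulus_for_motivation(0.50), "m1": stimulus_for_motivation(0.58)}
        prev = GOSState("c0", arousal=0.5, bout_length=4)
        _, gos = appraise(s, arch, prev, g)
        assert gos.dominant == "c1"
        assert gos.bout_length == 1

    def test_exactly_one_dominant_on_random_frames(self):
        arch = single_modality_arch(4)
        g = genome_for(arch, hyst=(0.02, 0.1))
        rng = child_rng(2, "frames")
        gos = GOSState("c0", arousal=0.0)
        for _ in range(2000):
            s = {f"m{i}": float(rng.uniform()) for i in range(4)}
            M, gos = appraise(s, arch, gos, g)
            assert gos.dominant in arch.ids
            assert all(0.0 <= v <= 1.0 for v in M.values())

    def test_hysteresis_reduces_switching(self):
        """On the same stream, a (0.1, 0.3) band switches no more than (0, 0)."""
        arch = single_modality_arch(3)
        rng = child_rng(3, "stream")
        stream = [{f"m{i}": float(rng.uniform()) for i in range(3)}
                  for _ in range(3000)]
        counts = {}
        for hyst in ((0.1, 0.3), (0.0, 0.0)):
            g = genome_for(arch, hyst=hyst)
            gos = GOSState("c0", arousal=0.0)
            switches = 0
            for s in stream:
                prev = gos.dominant
                _, gos = appraise(s, arch, gos, g)
                switches += gos.dominant != prev
            counts[hyst] = switches
        assert counts[(0.1, 0.3)] <= counts[(0.0, 0.0)]

    def test_threshold_non_increasing_in_arousal(self, genome):
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        thetas = [switching_threshold(genome, a) for a in levels]
        assert all(b <= a + 1e-12 for a, b in zip(thetas, thetas[1:]))
        assert thetas[0] == pytest.approx(genome.hysteresis_hi)
        assert thetas[-1] == pytest.approx(genome.hysteresis_lo)


class TestDissipate:
    def test_before_onset_identity(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, diss_rate=0.5, onset=10)
        gos = GOSState("c0", arousal=0.8, bout_length=9)
        assert dissipate(gos, g) == gos

    def test_single_step_decay(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, diss_rate=0.25, onset=5)
        gos = GOSState("c0", arousal=0.8, bout_length=5)
        out = dissipate(gos, g)
        assert out.arousal == pytest.approx(0.6)
        assert out.dominant == "c0"

    def test_repeated_decay_is_geometric(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, diss_rate=0.1, onset=1)
        gos = GOSState("c0", arousal=1.0, bout_length=1)
        for k in range(1, 8):
            gos = dissipate(gos, g)
            assert gos.arousal == pytest.approx(0.9 ** k)

    def test_disabled_flag_is_identity(self):
        arch = single_modality_arch(1)
        g = genome_for(arch, diss_rate=0.9, onset=1)
        gos = GOSState("c0", arousal=0.7, bout_length=50)
        assert dissipate(gos, g, enabled=False) == gos


def test_hill_is_bounded_and_half_saturating():
    assert hill(0.0, 2.0, 0.5) == 0.0
    assert hill(0.5, 3.0, 0.5) == pytest.approx(0.5)
    assert 0.0 <= hill(1.0, 4.0, 0.01) <= 1.0
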