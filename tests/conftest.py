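import pytest

from mitotempo.sequence_model import MitoProfile, VariantCall, load_reference


@pytest.fixture(scope="session")
def reference() -> str:
    return load_reference()


@pytest.fixture
def make_profile(reference):
    """Build a profile from haplotype-table-style substitution specs.

    ``make_profile("a1", 1000, "U5a", [(73, "G"), (263, "A")])`` — alt bases
    are adjusted to differ from the packaged reference automatically when the
    requested alt coincides with it.
    """

    def _make(pid: str, age_bp: float, haplogroup: str, subs=(), macro=None):
        variants = []
        for pos, alt in subs:
            ref_base = reference[pos - 1]
            if alt == ref_base:
                alt = next(b for b in "ACGT" if b != ref_base)
            variants.append(VariantCall(pos, "substitution", ref_base, alt))
        if macro is None:
            from mitotempo.sequence_model import infer_macrohaplogroup

            macro = infer_macrohaplogroup(haplogroup)
        return MitoProfile(
            id=pid,
            age_bp=age_bp,
            haplogroup=haplogroup,
            macrohaplogroup=macro,
            variants=frozenset(variants),
        )

    return _make
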