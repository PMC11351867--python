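"""Phantom generator: determinism, difficulty monotonicity, cohort splits."""

import numpy as np
import pytest

from cascadeseg.errors import ConfigurationError
from cascadeseg.synthetic_data import (PhantomSpec, generate_cohort,
                                       generate_phantom)


def lesion_contrast(sl, mask):
    """Channel-wise mean difference between lesion and non-lesion pixels."""
    inside = sl.pixels[mask.pixels]
    outside = sl.pixels[~mask.pixels]
    return inside.mean(axis=0) - outside.mean(axis=0)


class TestGeneratePhantom:
    def test_no_lesions_by_construction(self):
        spec = PhantomSpec(image_size=64, lesion_count_range=(0, 0), seed=1)
        _, mask = generate_phantom(spec)
        assert not mask.pixels.any()

    def test_determinism(self):
        spec = PhantomSpec(image_size=64, seed=9)
        s1, m1 = generate_phantom(spec)
        s2, m2 = generate_phantom(spec)
        assert np.array_equal(s1.pixels, s2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_difficulty_reduces_contrast(self):
        import dataclasses
        easy = PhantomSpec(image_size=64, lesion_count_range=(1, 3), seed=5,
                           difficulty=0.0)
        hard = dataclasses.replace(easy, difficulty=0.9)
        se, me = generate_phantom(easy)
        sh, mh = generate_phantom(hard)
        assert np.array_equal(me.pixels, mh.pixels)  # same geometry seed
        ce = lesion_contrast(se, me)
        ch = lesion_contrast(sh, mh)
        # contrast shrinks toward zero in each channel's own direction
        assert ce[1] < ch[1]   # dark channel: easy is more negative
        assert ce[2] > ch[2]   # bright channel: easy is more positive
        # identical geometry+noise: the easy-hard image difference equals
        # contrast * (difficulty gap) exactly on lesion pixels
        delta = (se.pixels - sh.pixels)[me.pixels]
        np.testing.assert_allclose(
            delta.mean(axis=0),
            0.9 * np.asarray(easy.contrast_per_channel), atol=1e-5)

    def test_channel_contrast_signs(self):
        spec = PhantomSpec(image_size=64, lesion_count_range=(2, 3), seed=2,
                           difficulty=0.0)
        sl, mask = generate_phantom(spec)
        c = lesion_contrast(sl, mask)
        assert c[1] < 0 < c[2]

    @pytest.mark.parametrize("field,kwargs", [
        ("image_size", {"image_size": 16}),
        ("noise_sd", {"noise_sd": 0.0}),
        ("lesion_radius_range", {"image_size": 64, "lesion_radius_range": (4, 40)}),
        ("difficulty", {"difficulty": 1.5}),
    ])
    def test_invalid_spec_names_field(self, field, kwargs):
        with pytest.raises(ConfigurationError, match=field):
            PhantomSpec(**kwargs)


class TestGenerateCohort:
    def test_split_sizes_rounding_exact(self):
        spec = PhantomSpec(image_size=32, seed=0)
        c = generate_cohort(spec, 10, slices_per_patient=2,
                            split_fractions=(0.6, 0.1, 0.3))
        assert (len(c.split("train")), len(c.split("val")), len(c.split("test"))) \
            == (6, 1, 3)

    def test_splits_disjoint(self):
        spec = PhantomSpec(image_size=32, seed=3)
        c = generate_cohort(spec, 11, slices_per_patient=2)
        ids = [set(p.patient_id for p in c.split(s))
               for s in ("train", "val", "test")]
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])

    def test_seed_changes_geometry(self):
        a = generate_cohort(PhantomSpec(image_size=32, seed=1), 3, 2)
        b = generate_cohort(PhantomSpec(image_size=32, seed=2), 3, 2)
        diff = any(
            not np.array_equal(sa.pixels, sb.pixels)
            for (sa, _), (sb, _) in zip(a.patients[0].slices, b.patients[0].slices))
        assert diff

    def test_bit_reproducible(self):
        spec = PhantomSpec(image_size=32, seed=4)
        a = generate_cohort(spec, 4, 3)
        b = generate_cohort(spec, 4, 3)
        for pa, pb in zip(a.patients, b.patients):
            assert pa.split == pb.split and pa.difficulty == pb.difficulty
            for (sa, ma), (sb, mb) in zip(pa.slices, pb.slices):
                assert np.array_equal(sa.pixels, sb.pixels)
                assert np.array_equal(ma.pixels, mb.pixels)

    def test_too_few_patients(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(PhantomSpec(seed=0), 2, 2)

    def test_lesion_fraction_bounded(self):
        """Lesion load stays under a quarter of the gland area per slice."""
        spec = PhantomSpec(image_size=64, seed=6, lesion_count_range=(0, 3))
        c = generate_cohort(spec, 8, slices_per_patient=6)
        for p in c.patients:
            for sl, mask in p.slices:
                gland_area = (sl.pixels[:, :, 0] > 0.35).sum()  # gland ~0.55
                assert mask.pixels.sum() <= 0.25 * max(gland_area, 1)

    def test_lesions_span_contiguous_slices(self):
        spec = PhantomSpec(image_size=32, seed=8, lesion_count_range=(1, 1))
        c = generate_cohort(spec, 4, slices_per_patient=8)
        for p in c.patients:
            with_lesion = [i for i, (_, m) in enumerate(p.slices)
                           if m.pixels.any()]
            if len(with_lesion) > 1:
                assert with_lesion == list(range(with_lesion[0],
                                                 with_lesion[-1] + 1))
                assert len(with_lesion) <= 4
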