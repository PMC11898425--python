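"""Baker-map cipher: key validation, the index formulas, bijectivity and
round-trip exactness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scramblenet import (
    BakerKey,
    CipherError,
    CipherKeyError,
    apply_permutation,
    baker_index_map,
    build_permutation,
    decrypt,
    encrypt,
    validate_baker_key,
)


def ordered_compositions(n, parts_allowed):
    """All ordered compositions of n from the allowed part sizes (oracle)."""
    if n == 0:
        yield ()
        return
    for p in parts_allowed:
        if p <= n:
            for rest in ordered_compositions(n - p, parts_allowed):
                yield (p,) + rest


class TestKeyValidation:
    def test_standard_demo_key_for_8(self):
        key = validate_baker_key((2, 4, 2), 8)
        assert key.parts == (2, 4, 2)
        assert key.offsets == (0, 2, 6)

    def test_single_block_key(self):
        key = validate_baker_key((8,), 8)
        assert key.offsets == (0,)

    @pytest.mark.parametrize(
        "parts, n, fragment",
        [
            ((3, 5), 8, "divide"),       # 3 does not divide 8
            ((2, 2), 8, "sum"),          # wrong total
            ((4, -2, 6), 8, "positive"), # negative part
            ((), 8, "at least one"),     # empty
        ],
    )
    def test_invalid_keys_rejected(self, parts, n, fragment):
        with pytest.raises(CipherKeyError, match=fragment):
            validate_baker_key(parts, n)

    def test_offsets_strictly_increasing_and_tile_grid(self):
        for n in (8, 12, 16):
            for parts in ordered_compositions(n, [d for d in range(1, n + 1) if n % d == 0]):
                key = validate_baker_key(parts, n)
                offs = key.offsets
                assert offs[0] == 0
                assert all(b > a for a, b in zip(offs, offs[1:]))
                assert offs[-1] + key.parts[-1] == n


class TestIndexMap:
    def test_hand_evaluated_pairs(self):
        # N=4, key (2,2): worked through the strip formulas by hand
        key = validate_baker_key((2, 2), 4)
        assert baker_index_map(1, 1, key) == (3, 0)
        assert baker_index_map(2, 3, key) == (1, 3)

    def test_single_block_key_is_identity(self):
        key = validate_baker_key((6,), 6)
        for r in range(6):
            for s in range(6):
                assert baker_index_map(r, s, key) == (r, s)

    def test_out_of_range_index_rejected(self):
        key = validate_baker_key((2, 2), 4)
        with pytest.raises(IndexError):
            baker_index_map(4, 0, key)
        with pytest.raises(IndexError):
            baker_index_map(0, -1, key)

    def test_table_matches_pointwise_map(self):
        # independent route: evaluate the scalar formula at all 16 indices
        key = validate_baker_key((2, 2), 4)
        img = np.arange(16, dtype=np.uint8).reshape(4, 4)
        expected = np.empty_like(img)
        for r in range(4):
            for s in range(4):
                r2, s2 = baker_index_map(r, s, key)
                expected[s2, r2] = img[s, r]
        table = build_permutation(key, 4)
        assert np.array_equal(apply_permutation(img, table), expected)


class TestBijectivityOracle:
    @pytest.mark.parametrize("n", [2, 4, 6, 8, 12, 16])
    def test_every_divisor_composition_is_a_bijection(self, n):
        divisors = [d for d in range(1, n + 1) if n % d == 0]
        count = 0
        for parts in ordered_compositions(n, divisors):
            key = validate_baker_key(parts, n)
            table = build_permutation(key, n)  # constructor verifies bijection
            assert np.array_equal(
                table.inverse[table.forward], np.arange(n * n)
            )
            count += 1
        assert count >= 1


class TestRandomKeyProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.sampled_from([8, 16, 24, 32, 48]))
    def test_random_keys_are_valid_and_bijective(self, seed, n):
        from scramblenet import random_baker_key

        key = random_baker_key(n, seed=seed)
        assert sum(key.parts) == n
        assert all(n % p == 0 for p in key.parts)
        assert key.parts != (n,)  # never the identity key
        table = build_permutation(key, n)  # constructor checks bijectivity
        assert np.array_equal(table.inverse[table.forward], np.arange(n * n))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_for_random_keys_and_images(self, seed):
        from scramblenet import random_baker_key

        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(24, 24), dtype=np.uint8)
        key = random_baker_key(24, seed=seed, rounds=int(rng.integers(1, 4)))
        assert np.array_equal(decrypt(encrypt(img, "baker", key), "baker", key), img)


class TestEncryptDecrypt:
    def test_round_trip_bit_exact(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            key = validate_baker_key((4, 8, 2, 2), 16, rounds=3)
            assert np.array_equal(decrypt(encrypt(img, "baker", key), "baker", key), img)

    def test_identity_key_returns_plaintext(self, random_image):
        key = validate_baker_key((64,), 64)
        assert np.array_equal(encrypt(random_image, "baker", key), random_image)

    def test_constant_image_is_fixed_point(self):
        img = np.full((8, 8), 128, dtype=np.uint8)
        key = validate_baker_key((2, 4, 2), 8)
        assert np.array_equal(encrypt(img, "baker", key), img)

    def test_histogram_exactly_conserved(self, random_image):
        key = validate_baker_key((8, 16, 32, 8), 64, rounds=2)
        enc = encrypt(random_image, "baker", key)
        assert np.array_equal(
            np.bincount(random_image.ravel(), minlength=256),
            np.bincount(enc.ravel(), minlength=256),
        )

    def test_rounds_compose_additively(self, random_image):
        parts = (2, 4, 2) + (8,) * 7
        a = validate_baker_key(parts, 64, rounds=2)
        b = validate_baker_key(parts, 64, rounds=3)
        ab = validate_baker_key(parts, 64, rounds=5)
        assert np.array_equal(
            encrypt(encrypt(random_image, "baker", a), "baker", b),
            encrypt(random_image, "baker", ab),
        )

    def test_size_mismatch_rejected(self, random_image):
        key = validate_baker_key((2, 2), 4)
        with pytest.raises(CipherError):
            encrypt(random_image, "baker", key)

    def test_non_square_image_rejected(self):
        key = validate_baker_key((2, 2), 4)
        with pytest.raises(CipherError, match="square"):
            encrypt(np.zeros((4, 6), dtype=np.uint8), "baker", key)
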