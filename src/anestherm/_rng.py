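"""Deterministic seed derivation.

A master seed is expanded into independent per-animal / per-signal substream
seeds by splitmix64-style integer hashing, so the seed of animal *i* does not
depend on how many animals were generated before it (order independence) and
the whole cohort is reproducible from one integer.
"""

_M64 = (1 << 64) - 1


def splitmix64(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return (z ^ (z >> 31)) & _M64


def derive_seed(master: int, *indices: int) -> int:
    """Hash (master, *indices) into a seed in [0, 2**31)."""
    z = splitmix64(int(master) & _M64)
    for ix in indices:
        z = splitmix64(z ^ splitmix64(int(ix) & _M64))
    return z & 0x7FFFFFFF
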