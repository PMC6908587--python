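# Deposited-structure cache

The deposited-coordinate acceptance tests (`tests/test_acceptance.py`,
`TestDepositedStructures`) read the four PDB entries they compare from this
directory as plain `.pdb` files, lower-case names:

    6rp5.pdb   carbonmonoxy Hb1Em, hexagonal form (displaced distal His)
    4esa.pdb   carbonmonoxy Hb1Em, orthorhombic form (canonical R state)
    3nfe.pdb   Hb1Tn deoxy (T-state reference)
    1t1n.pdb   Hb1Tn CO (R-state reference)

Coordinate files are not redistributed with the package. Populate the cache
once (network required):

```python
from hbstate.structure import fetch_structure
for acc in ("6rp5", "4esa", "3nfe", "1t1n"):
    fetch_structure(acc, "data/structures")
```

Everything else in the test suite is generated synthetically and runs fully
offline.
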