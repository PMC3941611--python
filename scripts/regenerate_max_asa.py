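#!/usr/bin/env python
"""Regenerate the frozen ALA-X-ALA maximum-ASA constants in betacv.tables.

Prints the two dictionaries (backbone and side-chain maxima, Å²) computed
from the ideal extended tripeptides at the default probe radius and sphere
resolution. The output should match tables.MAX_ASA_BB / MAX_ASA_SC.
"""

from betacv.asa import compute_max_asa_table


def main() -> None:
    bb, sc = compute_max_asa_table()
    for name, table in (("MAX_ASA_BB", bb), ("MAX_ASA_SC", sc)):
        print(f"{name} = {{")
        for res in sorted(table):
            print(f'    "{res}": {table[res]},')
        print("}")


if __name__ == "__main__":
    main()
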