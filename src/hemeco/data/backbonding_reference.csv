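# Synthetic literature-style backbonding correlation table (NOT a published
# compilation): representative (nu_CO, nu_FeCO) pairs for heme-CO complexes
# grouped by proximal-ligand class, used to fit reference correlation lines.
nu_CO_cm1,nu_FeCO_cm1,class
1904,534.5,His-proximal
1920,522.0,His-proximal
1932,514.0,His-proximal
1944,505.0,His-proximal
1951,499.5,His-proximal
1965,490.0,His-proximal
1920,498.5,thiolate
1940,483.5,thiolate
1958,471.0,thiolate
1963,467.0,thiolate
1948,525.5,weak-trans-5c
1955,520.0,weak-trans-5c
1965,512.5,weak-trans-5c
1975,505.0,weak-trans-5c
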