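year,start_doy,end_doy,d18o_wood_permil,d13c_wood_permil,d18o_cellulose_permil
2015,154,186,2.018512392806700e+01,-2.883776627016511e+01,2.458512392806700e+01
2015,165,192,2.015709830870023e+01,-2.878812887747119e+01,2.455709830870023e+01
2015,171,197,2.022976357368740e+01,-2.872103276108874e+01,2.462976357368740e+01
2015,177,202,2.031499777867692e+01,-2.865125219149157e+01,2.471499777867692e+01
2015,181,207,2.034619543401180e+01,-2.860491359429430e+01,2.474619543401180e+01
2015,186,213,2.053894823927146e+01,-2.856228436639864e+01,2.493894823927145e+01
2015,192,219,2.098220944773318e+01,-2.849187007296240e+01,2.538220944773317e+01
2015,198,228,2.133048784131937e+01,-2.848152519536752e+01,2.573048784131937e+01
2015,207,241,2.195225846394374e+01,-2.845203110264251e+01,2.635225846394373e+01
2015,221,264,2.216645581944606e+01,-2.855271219791101e+01,2.656645581944606e+01
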