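wavelength_nm,Hb,HbO2,AuNP
690,1.000000,0.134506,0.197899
700,0.874423,0.141328,0.278037
710,0.750736,0.153024,0.375311
720,0.646718,0.169594,0.486752
730,0.537145,0.190062,0.606531
740,0.543812,0.217353,0.726149
750,0.684828,0.252442,0.835270
760,0.754654,0.285581,0.923116
770,0.639330,0.316770,0.980199
780,0.524104,0.346011,1.000000
790,0.434122,0.368428,0.980199
800,0.371216,0.397669,0.923116
810,0.349461,0.421061,0.835270
820,0.338096,0.446402,0.726149
830,0.337745,0.474668,0.606531
840,0.337414,0.498060,0.486752
850,0.336907,0.515605,0.375311
860,0.337073,0.532174,0.278037
870,0.327550,0.549718,0.197899
880,0.317082,0.562389,0.135335
890,0.304860,0.574085,0.088922
900,0.297745,0.583832,0.056135
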