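# Reference set: CNVR intervals reported significantly associated with feeding
# traits in Nellore cattle (ARS-UCD1.2 coordinates, 1-based inclusive).
region_id	chromosome	start	end	type	trait
CNVR1	2	135110420	135653313	mixed	FF
CNVR2	5	117080458	117820070	deletion	FF
CNVR3	6	116755758	117164372	duplication	FF
CNVR4	7	10092268	10174209	duplication	FF
CNVR5	7	42951015	43292715	mixed	FF
CNVR6	7	43359066	43823809	mixed	FF
CNVR7	8	15562312	15781720	duplication	FF
CNVR8	8	38356510	38610355	duplication	FF
CNVR9	8	85996187	86508867	deletion	DMI
CNVR10	9	2637837	2700411	mixed	FF
CNVR11	9	16366613	16894948	duplication	FF
CNVR12	9	15312685	15469154	duplication	FF
CNVR13	12	73233249	73770215	mixed	FF
CNVR14	12	74302958	74578587	mixed	FF
CNVR15	12	64618237	64736496	duplication	FF
CNVR16	13	12552408	12829168	duplication	FF
CNVR17	26	51032219	51267717	duplication	FF
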