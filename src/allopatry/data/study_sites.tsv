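name	coordinate	plate	temperature	ph	origin
Fur	N37°46.385′W025°18.21′	Eurasian	55	2	Furnas, The Azores
Rib	N37°48.155′W025°29.16′	Eurasian	62	0–1	Ribeira Grande, The Azores
Fdl	N37°46.127′W025°19.89′	Eurasian	62–64	2–3	Furnas das Lagos, The Azores
Yel	N44°43.890′W110°42.682′	North American	50	2.8	Yellowstone National Park, United States
Ice	N63°53.278′W022°03.405′	Eurasian	60	3	Krysuvik, Iceland
Phi	N14°8.191′E121°13.262′	Philippine-boundary	55–65	3	Makiling mud spring, The Philippines
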