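label	ablated
wild_type
AVA-	AVA
AVB-	AVB
AVD-	AVD
AVE-	AVE
PVC-	PVC
DVA-	DVA
ASH-	ASH
ASH-AVA-	ASH,AVA
ASH-AVB-	ASH,AVB
ASH-AVA-AVB-	ASH,AVA,AVB
AVA-AVB-	AVA,AVB
AVD-AVE-	AVD,AVE
AVB-PVC-	AVB,PVC
AVA-AVD-AVE-	AVA,AVD,AVE
AVB-PVC-DVA-	AVB,PVC,DVA
AVD-AVE-DVA-	AVD,AVE,DVA
PVC-DVA-	PVC,DVA
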