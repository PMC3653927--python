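latin_name,common_name,assemblage,heath,thicket,flying_over,meadow,water,total
Fringilla montifringilla,Brambling,WCB,0,13,0,0,0,13
Carduelis flammea,Common Redpoll,WCB,25,466,185,1,0,677
Turdus pilaris,Fieldfare,WCB,13,125,27,10,0,175
Turdus iliacus,Redwing,WCB,16,201,9,4,0,230
Luscinia svecica,Bluethroat,WGB,1,102,0,2,1,106
Emberiza schoeniclus,Reed Bunting,WGB,0,19,0,0,0,19
Calidris temminckii,Temminck's Stint,WGB,0,5,7,18,1,31
Lagopus lagopus,Willow Ptarmigan,WGB,1,16,1,3,0,21
Phylloscopus trochilus,Willow Warbler,WGB,1,288,1,0,0,290
Pluvialis apricaria,Eurasian Golden Plover,OT,44,3,0,3,4,54
Calcarius lapponicus,Lapland Bunting,OT,56,126,2,15,0,199
Stercorarius longicaudus,Long-tailed Skua,OT,9,2,20,0,0,31
Anthus pratensis,Meadow Pipit,OT,257,213,16,76,0,562
Oenanthe oenanthe,Northern Wheatear,OT,18,8,0,5,0,31
Anthus cervinus,Red-throated Pipit,OT,6,23,2,2,0,33
Buteo lagopus,Rough-legged Buzzard,OT,9,0,1,0,0,10
Motacilla alba,White Wagtail,OT,16,23,8,5,8,60
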