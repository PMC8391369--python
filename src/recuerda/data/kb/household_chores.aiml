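<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="household_chores" description="actividades del hogar con las que el paciente disfrutaba ayudar">
    <category role="trigger">
      <pattern>QUEHACERES</pattern>
      <template><random>
        <li>Me contaron que disfrutabas <get name="tarea_hogar"/>. ¿Es verdad?</li>
        <li>Ayudar en casa deja bonitos recuerdos. ¿Con qué actividad disfrutabas ayudar?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ QUEHACERES</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>QUEHACERES _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ QUEHACERES _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>QUEHACER</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ QUEHACER</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>QUEHACER _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ QUEHACER _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>CASA</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CASA</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>CASA _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CASA _</pattern>
      <template><srai>QUEHACERES</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Qué bien! ¿Qué era lo que más te gustaba de <get name="tarea_hogar"/>?</li>
        <li>¿Quién te acompañaba cuando te tocaba <get name="tarea_hogar"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>No te preocupes. ¿En qué te gustaba ayudar en casa?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>La casa guarda muchas historias. ¿Me cuentas alguna?</li>
        <li>Un hogar se cuida entre todos. ¿Qué te tocaba hacer a ti?</li>
      </random></template>
    </category>
  </topic>
</aiml>
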